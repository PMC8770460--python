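"""End-to-end prognostic-panel discovery pipeline.

Chains every stage on a replicate-level cohort: replicate aggregation and
composite normalization, penetrance fold-change filtering, seed-iterated RFE
stability selection, additive boosted-logistic panel construction, stepwise
backward elimination plus AICc best-subset inference, and risk-score
survival stratification. All model choices (filter output, stability
ranking, peak panel, final subset, coefficients, cut-off) are learned on
cohort 1 and evaluated unchanged on cohort 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import aicc, panels, pfc, selection, survival
from .metrics import ROCResult, roc_metrics
from .preprocess import aggregate_replicates, composite_normalize
from .simulate import NON_SURVIVOR, RFUMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineSettings:
    """Tunable stage parameters; defaults are the full-scale study settings.

    Tests and the worked examples run scaled-down variants (fewer RFE
    iterations and smaller forests) that preserve every contract.
    """

    cv_threshold: float = 0.2
    ifc_threshold: float = 2.0
    pfc_min: float = 2.0
    pen_elevated_min: float = 10.0
    pen_other_max: float = 10.0
    directions: str = "both"
    rfe_iterations: int = 100
    rfe_trees: int = 500
    stability_k: int = 60
    cv_scheme: str = "5x10"
    boost_rounds: int = 100
    peak_tolerance: float = 0.0
    p_out: float = 0.05
    max_subset_size: int | None = 13
    enumeration_cap: int = 2**18
    positive_label: str = NON_SURVIVOR
    cox_covariates: tuple[str, ...] = ()


@dataclass
class PipelineResult:
    passing_probes: list[str]
    ranking: pd.DataFrame
    stable_probes: list[str]
    curve: pd.DataFrame
    peak_k: int
    reduced_probes: list[str]
    best_model: aicc.ModelCandidate
    roc_train: ROCResult
    roc_validation: ROCResult | None
    stratification: survival.RiskStratification
    normalized: pd.DataFrame = field(repr=False, default=None)


def run_pipeline(
    matrix: RFUMatrix,
    annotation: pd.DataFrame,
    settings: PipelineSettings | None = None,
    seed: int = 0,
) -> PipelineResult:
    s = settings or PipelineSettings()
    cohort = annotation["cohort"]
    labels = annotation["outcome"]

    norm = composite_normalize(aggregate_replicates(matrix, s.cv_threshold))
    values = norm.analyte_values()
    train = cohort == 1
    train_values = values.loc[train.to_numpy()]
    train_labels = labels.loc[train.to_numpy()]

    pfc_res = pfc.run_pfc(
        train_values, train_labels, threshold=s.ifc_threshold, pfc_min=s.pfc_min,
        pen_elevated_min=s.pen_elevated_min, pen_other_max=s.pen_other_max,
        directions=s.directions,
    )
    passing = pfc_res.probes
    logger.info("pFC filter retained %d/%d probes", len(passing), values.shape[1])
    if not passing:
        raise RuntimeError("no probes passed the penetrance filter")

    ranking = selection.rfe_stability(
        train_values[passing], train_labels, n_iter=s.rfe_iterations,
        panel_size_grid=(min(s.stability_k, len(passing)),), seed_base=seed,
        n_trees=s.rfe_trees,
    )
    stable = selection.select_stable(ranking, k=min(s.stability_k, len(passing)))

    curve = panels.additive_roc_curve(
        stable, train_values, train_labels, cv=s.cv_scheme, seed=seed,
        n_boost_rounds=s.boost_rounds, positive_label=s.positive_label,
    )
    peak_k = panels.pick_peak_panel(curve, tolerance=s.peak_tolerance)
    peak_panel = stable[:peak_k]

    if len(peak_panel) > 1 and len(train_labels) > len(peak_panel) + 1:
        reduced = aicc.backward_eliminate(
            train_values, train_labels, peak_panel, p_out=s.p_out
        )
    else:
        reduced = list(peak_panel)
    best, _ = aicc.best_parsimonious_model(
        train_values, train_labels, reduced,
        max_subset_size=s.max_subset_size,
        enumeration_cap=s.enumeration_cap, seed=seed,
    )

    scores = survival.risk_scores(best, values)
    y_all = (labels == s.positive_label).astype(int)
    roc_train = roc_metrics(scores[train].to_numpy(), y_all[train].to_numpy())
    roc_validation = None
    if (cohort == 2).any():
        val = cohort == 2
        roc_validation = roc_metrics(scores[val].to_numpy(), y_all[val].to_numpy())

    strat = survival.stratify(
        best, values, annotation, train_mask=train,
        cox_covariates=list(s.cox_covariates) or None,
    )
    return PipelineResult(
        passing_probes=passing, ranking=ranking, stable_probes=stable,
        curve=curve, peak_k=peak_k, reduced_probes=reduced, best_model=best,
        roc_train=roc_train, roc_validation=roc_validation,
        stratification=strat, normalized=values,
    )
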