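"""Additive cumulative panels evaluated with boosted logistic regression.

Panels are built by walking down the stability ranking cumulatively (1st
probe, 1st+2nd, 1st+2nd+3rd, ...) and scoring each nested panel with a
boosted logistic classifier under cross-validation, always on out-of-fold
scores. The classifier is componentwise LogitBoost: each boosting round fits
a one-variable weighted least-squares base learner to the working responses
of the logistic deviance and adds the best one to the additive score. The
panel curve (AUC / sensitivity / specificity versus panel size) is then
scanned for its peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .metrics import roc_metrics
from .simulate import NON_SURVIVOR

PROB_CLIP = 1e-6  # probability clipping against perfect separation


class BoostedLogit:
    """Componentwise LogitBoost for binary outcomes.

    Each round computes working responses z = (y - p) / (p(1-p)) and weights
    w = p(1-p), fits a one-variable least-squares learner a + b*x_j for every
    feature, and adds half the best learner (scaled by ``learning_rate``) to
    the additive score F. Training stops after ``n_rounds`` or when the
    training deviance improves by less than ``tol``.
    """

    def __init__(self, n_rounds: int = 100, learning_rate: float = 0.1,
                 tol: float = 1e-6):
        self.n_rounds = n_rounds
        self.learning_rate = learning_rate
        self.tol = tol
        self.stumps_: list[tuple[int, float, float]] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BoostedLogit":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        F = np.zeros(n)
        self.stumps_ = []
        prev_dev = np.inf
        for _ in range(self.n_rounds):
            p = np.clip(expit(F), PROB_CLIP, 1 - PROB_CLIP)
            w = p * (1 - p)
            z = (y - p) / w
            sw = w.sum()
            xm = (w[:, None] * X).sum(axis=0) / sw
            zm = (w * z).sum() / sw
            xc = X - xm
            zc = z - zm
            sxx = (w[:, None] * xc * xc).sum(axis=0)
            sxz = (w[:, None] * xc * zc[:, None]).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                b = np.where(sxx > 0, sxz / np.where(sxx > 0, sxx, 1.0), 0.0)
            # weighted SSE of each candidate learner
            sse = (w * zc**2).sum() - b * sxz
            j = int(np.argmin(sse))
            a = zm - b[j] * xm[j]
            self.stumps_.append((j, a, b[j]))
            F = F + self.learning_rate * 0.5 * (a + b[j] * X[:, j])
            p = np.clip(expit(F), PROB_CLIP, 1 - PROB_CLIP)
            dev = -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p)).sum()
            if prev_dev - dev < self.tol:
                break
            prev_dev = dev
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        F = np.zeros(len(X))
        for j, a, b in self.stumps_:
            F += self.learning_rate * 0.5 * (a + b * X[:, j])
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = np.clip(expit(self.decision_function(X)), PROB_CLIP, 1 - PROB_CLIP)
        return np.column_stack([1 - p, p])


@dataclass
class BoostFitResult:
    """A full-data fit plus out-of-fold scores with fold bookkeeping."""

    model: BoostedLogit
    oof_scores: pd.Series
    folds: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)


def _parse_cv(cv, y, seed):
    """Yield (train, test) index arrays for '<k>x<r>' repeated CV or 'loo'."""
    n = len(y)
    if cv == "loo":
        return list(LeaveOneOut().split(np.zeros(n), y)), 1
    if isinstance(cv, str) and "x" in cv:
        k, r = (int(v) for v in cv.split("x"))
    else:
        k, r = int(cv), 1
    splits = []
    for rep in range(r):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        splits.extend(skf.split(np.zeros(n), y))
    return splits, r


def boosted_logistic_fit(
    values: pd.DataFrame,
    labels: pd.Series,
    n_boost_rounds: int = 100,
    learning_rate: float = 0.1,
    cv: str = "5x10",
    seed: int = 0,
    positive_label: str = NON_SURVIVOR,
) -> BoostFitResult:
    """Fit the boosted logistic classifier and return out-of-fold scores.

    ``cv`` is ``"<folds>x<repeats>"`` for repeated stratified k-fold (default
    5-fold, 10 repeats) or ``"loo"``. Every sample's reported score comes
    only from models trained without it; repeated-CV scores are averaged
    across repeats.
    """
    if values.shape[1] == 0:
        raise ValueError("panel is empty")
    y = (labels.reindex(values.index) == positive_label).to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = values.to_numpy(dtype=float)

    splits, n_repeats = _parse_cv(cv, y, seed)
    score_sum = np.zeros(len(y))
    score_cnt = np.zeros(len(y))
    kept_splits = []
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2:
            continue  # degenerate fold (possible only under LOO at tiny n)
        m = BoostedLogit(n_rounds=n_boost_rounds, learning_rate=learning_rate)
        m.fit(X[tr], y[tr])
        score_sum[te] += m.decision_function(X[te])
        score_cnt[te] += 1
        kept_splits.append((tr, te))
    if (score_cnt == 0).any():
        raise ValueError("some samples received no out-of-fold score")

    full = BoostedLogit(n_rounds=n_boost_rounds, learning_rate=learning_rate)
    full.fit(X, y)
    oof = pd.Series(score_sum / score_cnt, index=values.index, name="oof_score")
    return BoostFitResult(model=full, oof_scores=oof, folds=kept_splits)


def additive_roc_curve(
    ordered_probes,
    values: pd.DataFrame,
    labels: pd.Series,
    cv: str = "5x10",
    seed: int = 0,
    n_boost_rounds: int = 100,
    positive_label: str = NON_SURVIVOR,
) -> pd.DataFrame:
    """ROC metrics for each nested cumulative panel along a ranking.

    Row k holds the out-of-fold AUC and the Youden-optimal sensitivity /
    specificity of the panel made of the first k probes.
    """
    ordered_probes = list(ordered_probes)
    if not ordered_probes:
        raise ValueError("need at least one ranked probe")
    y = (labels.reindex(values.index) == positive_label).astype(int)
    rows = []
    for k in range(1, len(ordered_probes) + 1):
        panel = ordered_probes[:k]
        try:
            fit = boosted_logistic_fit(
                values[panel], labels, n_boost_rounds=n_boost_rounds,
                cv=cv, seed=seed, positive_label=positive_label,
            )
        except ValueError as err:
            raise ValueError(f"additive panel k={k} failed: {err}") from err
        roc = roc_metrics(fit.oof_scores.to_numpy(), y.to_numpy())
        rows.append(
            {
                "k": k,
                "auc": roc.auc,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "probes": ",".join(panel),
                "cv": cv,
            }
        )
    return pd.DataFrame(rows)


def pick_peak_panel(curve: pd.DataFrame, tolerance: float = 0.0) -> int:
    """Smallest panel size whose AUC is within ``tolerance`` of the maximum."""
    if len(curve) == 0:
        raise ValueError("empty panel curve")
    aucs = curve["auc"].to_numpy()
    ks = curve["k"].to_numpy()
    ok = np.flatnonzero(aucs >= aucs.max() - tolerance)
    return int(ks[ok.min()])
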