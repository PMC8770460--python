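"""Marker ranking and stability selection.

Three filter rankings (rank-sum statistic, random-forest impurity importance,
mutual information on quartile-binned intensities) give quick univariate and
model-based orderings. The workhorse is seed-iterated recursive feature
elimination (RFE) with random forests: each iteration bootstraps the samples,
repeatedly fits a forest and drops the least-important 20% of probes until a
target panel size remains; a probe's *stability* is the fraction of
iterations in which it survives to the final retained set. Penalized
(elastic-net) logistic regression and a fold-change + FDR differential
reactivity test corroborate the stability set by independent routes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, mutual_info_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .simulate import NON_SURVIVOR, SURVIVOR

RANKING_COLUMNS = ["probe", "frequency", "mean_importance", "rank"]


def _check_two_classes(labels: pd.Series, min_per_class: int = 2) -> np.ndarray:
    y = (labels == NON_SURVIVOR).to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if (counts < min_per_class).any():
        raise ValueError(f"need >= {min_per_class} samples per class, got {counts}")
    return y


def _scores_to_ranks(scores: np.ndarray, probes) -> np.ndarray:
    """Rank 1..n by descending score, ties broken by probe id (ascending)."""
    order = np.lexsort((np.asarray(probes, dtype=object), -scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def rank_by_filters(
    values: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Three complete probe rankings: rank-sum, RF importance, mutual info.

    Constant probes are assigned the worst ranks in every method. Mutual
    information is estimated on quartile-binned values (deterministic and
    scale-free); the rank-sum score is the absolute distance of the
    Mann-Whitney U statistic from its null mean.
    """
    y = _check_two_classes(labels)
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    probes = list(values.columns)
    constant = np.ptp(X, axis=0) == 0

    # rank-sum: |U - n1*n0/2| from average ranks, vectorized over probes
    ranks = stats.rankdata(X, axis=0)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    u1 = ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    ranksum_score = np.abs(u1 - n1 * n0 / 2.0)

    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    ).fit(X, y)
    rf_score = rf.feature_importances_.copy()

    mi_score = np.empty(p)
    for j in range(p):
        col = X[:, j]
        if constant[j]:
            mi_score[j] = 0.0
            continue
        qs = np.quantile(col, [0.25, 0.5, 0.75])
        binned = np.searchsorted(np.unique(qs), col, side="left")
        mi_score[j] = mutual_info_score(y, binned)

    out = pd.DataFrame({"probe": probes})
    for name, score in (
        ("ranksum", ranksum_score),
        ("rf_importance", rf_score),
        ("mutual_info", mi_score),
    ):
        score = np.where(constant, -np.inf, score)
        out[f"{name}_score"] = score
        out[f"{name}_rank"] = _scores_to_ranks(score, probes)
    return out


def rfe_stability(
    values: pd.DataFrame,
    labels: pd.Series,
    n_iter: int = 100,
    panel_size_grid=(60,),
    seed_base: int = 0,
    n_trees: int = 500,
    drop_fraction: float = 0.2,
    bootstrap: bool = True,
) -> pd.DataFrame:
    """Seed-iterated RFE with random-forest importance.

    Each iteration i (seeded ``seed_base + i``) optionally bootstraps the
    samples, then alternates forest fitting with elimination of the
    lowest-importance ``drop_fraction`` of probes until ``min(panel_size_grid)``
    remain. Returns the StabilityRanking: per probe its selection frequency,
    mean importance in the final retained fit when selected, and a total
    stability rank (frequency desc, mean importance desc, probe id asc).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    target = int(min(panel_size_grid))
    y_all = _check_two_classes(labels)
    X_all = values.to_numpy(dtype=float)
    probes = np.asarray(values.columns, dtype=object)
    if target > len(probes):
        raise ValueError("panel size grid exceeds the number of probes")

    counts = np.zeros(len(probes))
    imp_sums = np.zeros(len(probes))
    for i in range(n_iter):
        rng = np.random.default_rng(seed_base + i)
        if bootstrap:
            for _ in range(100):
                idx = rng.integers(0, len(X_all), size=len(X_all))
                if len(np.unique(y_all[idx])) == 2:
                    break
            X, y = X_all[idx], y_all[idx]
        else:
            X, y = X_all, y_all
        keep = np.arange(len(probes))
        rf_seed = int(rng.integers(0, 2**31 - 1))
        while True:
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=rf_seed,
                n_jobs=1,
            ).fit(X[:, keep], y)
            imp = rf.feature_importances_
            if len(keep) <= target:
                break
            n_drop = max(1, int(np.floor(drop_fraction * len(keep))))
            n_drop = min(n_drop, len(keep) - target)
            keep = keep[np.argsort(-imp, kind="stable")[: len(keep) - n_drop]]
        counts[keep] += 1
        imp_sums[keep] += imp

    freq = counts / n_iter
    with np.errstate(invalid="ignore"):
        mean_imp = np.where(counts > 0, imp_sums / np.maximum(counts, 1), np.nan)
    sort_imp = np.where(np.isnan(mean_imp), -np.inf, mean_imp)
    order = np.lexsort((probes, -sort_imp, -freq))
    rank = np.empty(len(probes), dtype=int)
    rank[order] = np.arange(1, len(probes) + 1)
    out = pd.DataFrame(
        {
            "probe": probes,
            "frequency": freq,
            "mean_importance": mean_imp,
            "rank": rank,
        }
    ).sort_values("rank", ignore_index=True)
    return out


def select_stable(ranking: pd.DataFrame, k: int = 60) -> list[str]:
    """First ``k`` probes by stability rank (rank order preserved)."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} ranked probes")
    ordered = ranking.sort_values("rank")
    return list(ordered["probe"].iloc[:k])


def lasso_corroborate(
    values: pd.DataFrame,
    labels: pd.Series,
    elastic_net_alpha: float = 0.9,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
    n_penalties: int = 25,
) -> pd.Series:
    """Elastic-net logistic selection with repeated CV and the 1-SE rule.

    The mixing parameter (0.9 by default, near-lasso) trades sparsity for
    numerical stability under probe collinearity. The penalty strength is
    chosen as the strongest penalty whose repeated cross-validated deviance
    is within one standard error of the minimum. Returns the nonzero
    coefficients (probe -> coefficient) of the refit on all samples.
    """
    y = _check_two_classes(labels, min_per_class=folds)
    X = StandardScaler().fit_transform(values.to_numpy(dtype=float))
    Cs = np.logspace(-3, 2, n_penalties)

    def _fit(C: float, Xtr, ytr) -> LogisticRegression:
        return LogisticRegression(
            l1_ratio=elastic_net_alpha,
            C=C,
            solver="saga",
            max_iter=5000,
            tol=1e-4,
        ).fit(Xtr, ytr)

    for attempt in range(5):
        cv = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=repeats, random_state=seed + attempt
        )
        splits = list(cv.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
    else:
        raise ValueError("could not form folds with both classes present")

    dev = np.empty((len(Cs), len(splits)))
    for ci, C in enumerate(Cs):
        for si, (tr, te) in enumerate(splits):
            model = _fit(C, X[tr], y[tr])
            prob = model.predict_proba(X[te])[:, 1]
            dev[ci, si] = log_loss(y[te], prob, labels=[0, 1])
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(dev.shape[1])
    best = int(np.argmin(mean_dev))
    # 1-SE rule: strongest penalty (smallest C) within one SE of the minimum
    within = np.flatnonzero(mean_dev <= mean_dev[best] + se_dev[best])
    chosen = Cs[int(within.min())]

    final = _fit(chosen, X, y)
    coefs = pd.Series(final.coef_.ravel(), index=values.columns)
    return coefs[coefs.abs() > 1e-8]


def differential_reactivity(
    values: pd.DataFrame,
    labels: pd.Series,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Differential reactivity: group fold-change + rank-sum test + BH FDR.

    Fold-change is survivor mean / non-survivor mean on the normalized
    scale; probes with (FC >= ``fc_high`` or FC <= ``fc_low``) and BH
    q <= ``q_max`` pass (inclusive comparisons). Returns per-probe fc, p, q
    and the boolean verdict.
    """
    _check_two_classes(labels)
    surv = values.loc[(labels == SURVIVOR).to_numpy()]
    nonsurv = values.loc[(labels == NON_SURVIVOR).to_numpy()]
    fc = surv.mean(axis=0) / nonsurv.mean(axis=0)

    pvals = np.empty(values.shape[1])
    for j, probe in enumerate(values.columns):
        a, b = surv[probe].to_numpy(), nonsurv[probe].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[j] = 1.0
        else:
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]

    out = pd.DataFrame(
        {"probe": values.columns, "fc": fc.to_numpy(), "p": pvals, "q": qvals}
    )
    out["pass"] = ((out["fc"] >= fc_high) | (out["fc"] <= fc_low)) & (
        out["q"] <= q_max
    )
    return out
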