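"""ROC machinery shared by all pipeline stages.

AUC is the two-sample rank statistic (ties get half credit), its variance
and confidence interval come from the DeLong structural-components method,
and operating points are picked by Youden's J (ties toward higher
specificity, then lower threshold). ``auc_compare`` is the DeLong test for
the difference of two AUCs, paired (shared samples, covariance between the
two score vectors) or unpaired (independent cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    n_pos: int
    n_neg: int


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """AUC and the DeLong placement values V10 (per positive), V01 (per negative)."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    mid = stats.rankdata(all_scores)  # midranks handle ties
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    auc = (mid[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (mid[:m] - rank_pos) / n
    v01 = 1.0 - (mid[m:] - rank_neg) / m
    return auc, v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimator)."""
    pos, neg = _split_scores(scores, labels)
    auc, v10, v01 = _delong_components(pos, neg)
    var = _var(v10) / len(pos) + _var(v01) / len(neg)
    return auc, var


def _var(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if len(v) > 1 else 0.0


def youden_operating_point(scores, labels) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing J = sens + spec - 1.

    Thresholds are midpoints of adjacent sorted unique scores (positive
    predicted when score >= threshold); ties on J break toward higher
    specificity, then lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("scores are constant; no operating point exists")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for t in cuts:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


def roc_metrics(scores, labels, operating_rule: str = "youden") -> ROCResult:
    """AUC with DeLong 95% CI and the operating-point sensitivity/specificity.

    ``labels`` are 0/1 with 1 the positive (prognostic-event) class; higher
    scores indicate the positive class. ``operating_rule`` is ``"youden"`` or
    ``"closest"`` (closest point to (0, 1) in ROC space).
    """
    pos, neg = _split_scores(scores, labels)
    auc, var = delong_variance(scores, labels)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(scores)) < 2:
        thr, sens, spec = float(scores[0]), 1.0, 0.0
    elif operating_rule == "youden":
        thr, sens, spec = youden_operating_point(scores, labels)
    elif operating_rule == "closest":
        thr, sens, spec = _closest_operating_point(scores, labels)
    else:
        raise ValueError(f"unknown operating rule {operating_rule!r}")
    return ROCResult(
        auc=float(auc), auc_ci=ci, sensitivity=float(sens),
        specificity=float(spec), threshold=float(thr),
        n_pos=len(pos), n_neg=len(neg),
    )


def _closest_operating_point(scores, labels):
    uniq = np.unique(scores)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best = None
    for t in cuts:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        d2 = (1 - sens) ** 2 + (1 - spec) ** 2
        key = (-round(d2, 12), round(spec, 12), -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


def auc_compare(scores_a, labels_a, scores_b, labels_b, paired: bool = False) -> float:
    """Two-sided DeLong p-value for the difference between two AUCs.

    Paired comparison requires the two score vectors to cover the same
    samples in the same order (identical labels); the covariance of the
    placement values then enters the variance of the difference. Unpaired
    comparison sums the two independent DeLong variances.
    """
    if paired:
        la = np.asarray(labels_a)
        lb = np.asarray(labels_b)
        if len(la) != len(lb) or (la != lb).any():
            raise ValueError("paired comparison requires identical sample sets")
        pos_a, neg_a = _split_scores(scores_a, la)
        pos_b, neg_b = _split_scores(scores_b, lb)
        auc_a, v10_a, v01_a = _delong_components(pos_a, neg_a)
        auc_b, v10_b, v01_b = _delong_components(pos_b, neg_b)
        m, n = len(pos_a), len(neg_a)
        var = (
            _var(v10_a) + _var(v10_b) - 2 * _cov(v10_a, v10_b)
        ) / m + (_var(v01_a) + _var(v01_b) - 2 * _cov(v01_a, v01_b)) / n
    else:
        auc_a, var_a = delong_variance(scores_a, labels_a)
        auc_b, var_b = delong_variance(scores_b, labels_b)
        var = var_a + var_b

    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _cov(u: np.ndarray, v: np.ndarray) -> float:
    if len(u) < 2:
        return 0.0
    return float(np.cov(u, v, ddof=1)[0, 1])
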