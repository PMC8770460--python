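"""AICc multi-model inference over marker subsets.

The peak additive panel is first reduced by stepwise backward elimination in
a multivariate logistic regression (likelihood-ratio drop tests). Candidate
subsets of the reduced panel are then scored with the small-sample
corrected Akaike criterion,

    AIC  = -2 logL + 2K,
    AICc = AIC + 2K(K+1) / (n - K - 1),

with K the parameter count (probes + intercept) and logL the maximized
logistic log-likelihood. Akaike weights, exp(-delta_i/2) normalized over the
candidate family, quantify the relative evidence for each model; the
lowest-AICc candidate is the most parsimonious model. Enumeration is
exhaustive up to a fit-count cap and falls back to a seeded genetic search
beyond it.

Logistic fits use a compact Newton (IRLS) solver so that enumerating up to
2^18 subsets stays cheap; a small ridge stabilizes separated fits.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RIDGE_FALLBACK = 1e-4


def logistic_fit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                 max_iter: int = 100, tol: float = 1e-10):
    """Newton/IRLS maximum-likelihood logistic regression.

    ``X`` includes the intercept column. Returns (beta, logL, converged).
    On divergence (separation) the caller should refit with a small ridge.
    """
    n, k = X.shape
    beta = np.zeros(k)
    prev_ll = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(p) + (1 - y) @ np.log(1 - p))
        if ridge:
            ll -= 0.5 * ridge * float(beta @ beta)
        w = p * (1 - p)
        grad = X.T @ (y - p) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(k)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        beta = beta + step
        if abs(ll - prev_ll) < tol:
            return beta, ll, True
        if np.abs(beta).max() > 1e3:  # runaway coefficients: separation
            return beta, ll, False
        prev_ll = ll
    return beta, prev_ll, True


def _fit_subset(X: np.ndarray, y: np.ndarray):
    """Fit with intercept; ridge-stabilized retry on separation/divergence."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, ll, ok = logistic_fit(Xd, y, ridge=0.0)
    if not ok:
        logger.warning("separation detected; refitting with ridge %g", RIDGE_FALLBACK)
        beta, ll, ok = logistic_fit(Xd, y, ridge=RIDGE_FALLBACK)
    return beta, ll


@dataclass
class ModelCandidate:
    """A marker subset with its likelihood and information-criterion scores."""

    probes: tuple[str, ...]
    n: int
    K: int
    logL: float
    aic: float
    aicc: float
    coefficients: pd.Series = field(repr=False, default=None)
    delta: float = math.nan
    weight: float = math.nan


def _encode_labels(labels: pd.Series) -> np.ndarray:
    from .simulate import NON_SURVIVOR

    return (labels == NON_SURVIVOR).to_numpy().astype(float)


def model_likelihood_aicc(
    values: pd.DataFrame, labels: pd.Series, subset
) -> ModelCandidate:
    """Maximum-likelihood logistic fit of one subset, scored by AIC and AICc.

    K counts the intercept, so the intercept-only model has K = 1; AICc is
    undefined (error) when n <= K + 1.
    """
    subset = tuple(subset)
    y = _encode_labels(labels.reindex(values.index))
    n = len(y)
    K = len(subset) + 1
    if n <= K + 1:
        raise ValueError(f"AICc undefined: n={n} <= K+1={K + 1}")
    X = values[list(subset)].to_numpy(dtype=float) if subset else np.empty((n, 0))
    beta, ll = _fit_subset(X, y)
    aic = -2.0 * ll + 2.0 * K
    aicc = aic + 2.0 * K * (K + 1) / (n - K - 1)
    coefs = pd.Series(beta, index=["intercept", *subset])
    return ModelCandidate(
        probes=subset, n=n, K=K, logL=ll, aic=aic, aicc=aicc, coefficients=coefs
    )


def akaike_weights(candidates: list[ModelCandidate]) -> list[ModelCandidate]:
    """Fill delta (AICc - min AICc) and Akaike weight for a candidate family."""
    if not candidates:
        raise ValueError("empty candidate set")
    aiccs = np.array([c.aicc for c in candidates])
    deltas = aiccs - aiccs.min()
    w = np.exp(-deltas / 2.0)
    w /= w.sum()
    for c, d, wi in zip(candidates, deltas, w):
        c.delta = float(d)
        c.weight = float(wi)
    return candidates


def backward_eliminate(
    values: pd.DataFrame, labels: pd.Series, probes, p_out: float = 0.05
) -> list[str]:
    """Stepwise backward elimination by likelihood-ratio drop tests.

    Iteratively refits the multivariate logistic model and removes the probe
    with the largest LR p-value while it exceeds ``p_out``; stops when every
    remaining probe is significant or one probe remains.
    """
    probes = list(probes)
    if not probes:
        raise ValueError("empty probe list")
    y = _encode_labels(labels.reindex(values.index))
    if len(y) <= len(probes) + 1:
        raise ValueError("need n > number of probes + 1")

    current = list(probes)
    while len(current) > 1:
        X = values[current].to_numpy(dtype=float)
        _, ll_full = _fit_subset(X, y)
        pvals = []
        for j in range(len(current)):
            Xr = np.delete(X, j, axis=1)
            _, ll_red = _fit_subset(Xr, y)
            lr = max(0.0, 2.0 * (ll_full - ll_red))
            pvals.append(stats.chi2.sf(lr, df=1))
        worst = int(np.argmax(pvals))
        if pvals[worst] <= p_out:
            break
        current.pop(worst)
    return current


def _subset_count(p: int, max_size: int) -> int:
    return sum(math.comb(p, s) for s in range(1, max_size + 1))


def best_parsimonious_model(
    values: pd.DataFrame,
    labels: pd.Series,
    probes,
    max_subset_size: int | None = None,
    enumeration_cap: int = 2**18,
    seed: int = 0,
) -> tuple[ModelCandidate, list[ModelCandidate]]:
    """Lowest-AICc subset of ``probes``, with the full weighted candidate table.

    All non-empty subsets up to ``max_subset_size`` are enumerated when their
    count fits in ``enumeration_cap``; otherwise a seeded genetic search over
    subset indicator masks explores the space and the weights are computed
    over the evaluated family.
    """
    probes = list(probes)
    if not probes:
        raise ValueError("empty probe list")
    max_size = len(probes) if max_subset_size is None else min(max_subset_size,
                                                               len(probes))
    total = _subset_count(len(probes), max_size)
    if total <= enumeration_cap:
        candidates = [
            model_likelihood_aicc(values, labels, subset)
            for size in range(1, max_size + 1)
            for subset in itertools.combinations(probes, size)
        ]
    else:
        logger.info(
            "subset count %d exceeds cap %d; using genetic search", total,
            enumeration_cap,
        )
        candidates = _genetic_search(values, labels, probes, max_size, seed)
    akaike_weights(candidates)
    best = min(candidates, key=lambda c: (c.aicc, c.probes))
    return best, candidates


def _genetic_search(
    values, labels, probes, max_size, seed,
    population: int = 120, generations: int = 60, mutation_rate: float = 0.05,
) -> list[ModelCandidate]:
    rng = np.random.default_rng(seed)
    p = len(probes)
    cache: dict[tuple, ModelCandidate] = {}

    def evaluate(mask: np.ndarray) -> ModelCandidate:
        idx = np.flatnonzero(mask)
        if idx.size == 0 or idx.size > max_size:
            # repair: random valid size
            size = int(rng.integers(1, max_size + 1))
            idx = rng.choice(p, size=size, replace=False)
        key = tuple(sorted(idx))
        if key not in cache:
            cache[key] = model_likelihood_aicc(
                values, labels, [probes[i] for i in key]
            )
        return cache[key]

    pop = (rng.uniform(size=(population, p)) < min(0.5, max_size / p)).astype(bool)
    for _ in range(generations):
        fits = np.array([evaluate(m).aicc for m in pop])
        order = np.argsort(fits)
        elite = pop[order[: population // 4]]
        children = [e for e in elite]
        while len(children) < population:
            a, b = elite[rng.integers(0, len(elite), size=2)]
            cross = rng.uniform(size=p) < 0.5
            child = np.where(cross, a, b)
            flip = rng.uniform(size=p) < mutation_rate
            child = child ^ flip
            children.append(child)
        pop = np.array(children)
    for m in pop:
        evaluate(m)
    return list(cache.values())


def candidate_table(candidates: list[ModelCandidate]) -> pd.DataFrame:
    rows = [
        {
            "subset": ",".join(c.probes),
            "K": c.K,
            "logL": c.logL,
            "AIC": c.aic,
            "AICc": c.aicc,
            "delta": c.delta,
            "weight": c.weight,
        }
        for c in sorted(candidates, key=lambda c: c.aicc)
    ]
    return pd.DataFrame(rows)
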