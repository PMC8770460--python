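"""Replicate aggregation, composite normalization and basic array QC.

The array prints each probe in replicate (quadruplicate by default); spots
sharing a probe share biology and differ by technical noise, so the
sample-probe value is the replicate median and a replicate CV above threshold
flags the measurement. Normalization is two-stage "composite": an
intensity module anchors every array to its positive-control probes (the
control-probe geometric mean is equalised across samples, removing
array-wide labelling/scanning effects), then a quantile module equalises the
analyte intensity distributions across samples. Control probes are carried
through but excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import RFUMatrix


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """Samples x probes single-value RFU matrix with QC flags.

    ``cv_flags`` marks sample-probe cells whose replicate CV exceeded the
    aggregation threshold (or whose replicates were all invalid);
    ``sample_flags`` marks whole arrays where >20% of analyte probes were
    CV-flagged.
    """

    values: pd.DataFrame
    cv_flags: pd.DataFrame
    sample_flags: pd.Series
    control_probes: frozenset[str]

    @property
    def analyte_probes(self) -> list[str]:
        return [p for p in self.values.columns if p not in self.control_probes]

    def analyte_values(self) -> pd.DataFrame:
        """Values restricted to analyte probes (what downstream stages use)."""
        return self.values[self.analyte_probes]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.6f")


ARRAY_FLAG_FRACTION = 0.2  # >20% CV-flagged analyte probes fails the array


def aggregate_replicates(
    matrix: RFUMatrix, cv_threshold: float = 0.2
) -> NormalizedMatrix:
    """Collapse replicate spots to one value per sample-probe (median).

    The replicate CV (sample SD / mean) above ``cv_threshold`` sets the QC
    flag; probes whose replicates are all non-positive get a NaN value and a
    flag. A single replicate aggregates to itself, unflagged.
    """
    wide = matrix.values
    probes = matrix.probe_ids
    n_rep = matrix.n_replicates
    arr = wide.to_numpy().reshape(len(wide), len(probes), n_rep)

    valid = arr > 0
    all_invalid = ~valid.any(axis=2)
    med = np.median(arr, axis=2)
    med[all_invalid] = np.nan

    mean = arr.mean(axis=2)
    if n_rep > 1:
        sd = arr.std(axis=2, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
    else:
        cv = np.zeros_like(mean)
    flags = (cv > cv_threshold) | all_invalid

    values = pd.DataFrame(med, index=wide.index, columns=probes)
    cv_flags = pd.DataFrame(flags, index=wide.index, columns=probes)
    analytes = [p for p in probes if p not in matrix.control_probes]
    sample_flags = cv_flags[analytes].mean(axis=1) > ARRAY_FLAG_FRACTION
    return NormalizedMatrix(
        values=values,
        cv_flags=cv_flags,
        sample_flags=sample_flags,
        control_probes=frozenset(matrix.control_probes),
    )


def _geomean(x: np.ndarray, axis=None) -> np.ndarray:
    return np.exp(np.log(x).mean(axis=axis))


def _quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows (samples) of X against the mean sorted profile.

    Tied values within a sample receive the mean of the target quantiles
    their rank span covers, so ties stay tied and the map is deterministic.
    """
    n, p = X.shape
    target = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X, dtype=float)
    for i in range(n):
        order = np.argsort(X[i], kind="mergesort")
        sorted_v = X[i][order]
        # contiguous runs of equal values share the mean target over the run
        starts = np.flatnonzero(np.r_[True, sorted_v[1:] != sorted_v[:-1]])
        counts = np.diff(np.r_[starts, p])
        sums = np.add.reduceat(target, starts)
        out[i, order] = np.repeat(sums / counts, counts)
    return out


def composite_normalize(
    matrix: NormalizedMatrix, control_probes=None
) -> NormalizedMatrix:
    """Two-stage composite normalization.

    Stage 1 (intensity module): rescale each sample so its control-probe
    geometric mean equals the across-sample grand geometric mean of control
    probes. Stage 2 (quantile module): quantile-normalize analyte probes
    across samples. Idempotent: a second application is a numerical no-op.
    """
    controls = sorted(control_probes if control_probes is not None
                      else matrix.control_probes)
    if len(controls) < 2:
        raise NormalizationError("composite normalization needs >= 2 control probes")
    missing = [c for c in controls if c not in matrix.values.columns]
    if missing:
        raise NormalizationError(f"control probes missing from matrix: {missing}")
    if len(matrix.values) < 2:
        raise NormalizationError("composite normalization needs >= 2 samples")

    values = matrix.values.copy()
    ctrl = values[controls].to_numpy()
    per_sample = _geomean(ctrl, axis=1)
    grand = _geomean(per_sample)
    scale = grand / per_sample
    values = values.mul(scale, axis=0)

    analytes = [p for p in values.columns if p not in set(controls)]
    values[analytes] = _quantile_normalize(values[analytes].to_numpy())

    return replace(matrix, values=values, control_probes=frozenset(controls))
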