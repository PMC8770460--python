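"""Penetrance fold-change (pFC) analysis.

The pFC statistic looks for markers that are strongly elevated in a *subset*
of one outcome group — the penetrance structure typical of autoantibody
responses, where only some patients mount a response but responders do so at
high titre. For probe A and sample X,

    IFC(A, X) = RFU(A, X) / mean RFU(A, control group)

i.e. each sample's intensity relative to the mean of a reference outcome
group. Within a group, the penetrance frequency is the percentage of samples
with IFC at or above a threshold (default 2), and the group pFC is the mean
IFC over exactly those threshold-passers (undefined when none pass).

A probe passes the filter in a direction (elevated in survivors, or in
non-survivors) when (i) the elevated group's pFC >= 2, (ii) the elevated
group's penetrance frequency >= 10%, and (iii) the other group's penetrance
frequency <= 10% — all comparisons inclusive. The reference group in the IFC
denominator is the opposite outcome group for each direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import NON_SURVIVOR, SURVIVOR

_OTHER = {SURVIVOR: NON_SURVIVOR, NON_SURVIVOR: SURVIVOR}

# PenetranceTable columns (long format, one row per probe x direction)
PFC_COLUMNS = [
    "probe",
    "direction",
    "pfc_survivor",
    "pen_freq_survivor",
    "pfc_nonsurvivor",
    "pen_freq_nonsurvivor",
]


def compute_ifc(
    values: pd.DataFrame, labels: pd.Series, control_group: str
) -> pd.DataFrame:
    """Individual fold-changes of every sample against a reference group mean.

    Probes whose control-group mean is zero or undefined are dropped (listed
    in ``result.attrs["excluded_probes"]``). Control-group members are
    included in the output, so their per-probe mean IFC is exactly 1.
    """
    labels = labels.reindex(values.index)
    mask = (labels == control_group).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    denom = values.loc[mask].mean(axis=0)
    bad = ~(denom > 0) | ~np.isfinite(denom)
    excluded = list(denom.index[bad])
    ifc = values.loc[:, ~bad].div(denom[~bad], axis=1)
    ifc.attrs["excluded_probes"] = excluded
    ifc.attrs["control_group"] = control_group
    return ifc


def penetrance_stats(
    ifc: pd.DataFrame, labels: pd.Series, threshold: float = 2.0
) -> pd.DataFrame:
    """Per-probe penetrance frequency (%) and pFC for both outcome groups.

    pFC is the mean IFC over the samples at or above ``threshold``; it is
    recorded as NaN (absent) when no sample in the group passes.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    labels = labels.reindex(ifc.index)
    out = pd.DataFrame(index=ifc.columns)
    for group, suffix in ((SURVIVOR, "survivor"), (NON_SURVIVOR, "nonsurvivor")):
        sub = ifc.loc[(labels == group).to_numpy()]
        if len(sub) == 0:
            raise ValueError(f"group {group!r} is empty")
        passes = sub.to_numpy() >= threshold
        n_pass = passes.sum(axis=0)
        out[f"pen_freq_{suffix}"] = 100.0 * n_pass / len(sub)
        with np.errstate(invalid="ignore"):
            pfc = np.where(
                n_pass > 0,
                np.nansum(np.where(passes, sub.to_numpy(), 0.0), axis=0)
                / np.maximum(n_pass, 1),
                np.nan,
            )
        out[f"pfc_{suffix}"] = pfc
    out.index.name = "probe"
    return out


def penetrance_analysis(
    values: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 2.0,
    directions: str = "both",
) -> pd.DataFrame:
    """Build the full PenetranceTable, one row per probe x direction.

    For each direction the IFC denominator is the opposite outcome group's
    mean, so the two directions generally come from different IFC matrices.
    """
    dirs = _resolve_directions(directions)
    blocks = []
    for elevated in dirs:
        ifc = compute_ifc(values, labels, control_group=_OTHER[elevated])
        stats = penetrance_stats(ifc, labels, threshold=threshold)
        stats = stats.reset_index()
        stats.insert(1, "direction", elevated)
        blocks.append(stats)
    table = pd.concat(blocks, ignore_index=True)
    return table[PFC_COLUMNS + [c for c in table.columns if c not in PFC_COLUMNS]]


def _resolve_directions(directions: str) -> list[str]:
    if directions == "both":
        return [SURVIVOR, NON_SURVIVOR]
    if directions in (SURVIVOR, NON_SURVIVOR):
        return [directions]
    raise ValueError(f"unknown directions {directions!r}")


def pfc_filter(
    table: pd.DataFrame,
    pfc_min: float = 2.0,
    pen_elevated_min: float = 10.0,
    pen_other_max: float = 10.0,
    directions: str = "both",
) -> pd.DataFrame:
    """Apply the three-criterion penetrance filter; returns passing rows.

    A row with direction d passes when group d satisfies pFC >= ``pfc_min``
    and penetrance >= ``pen_elevated_min`` (%), and the other group's
    penetrance is <= ``pen_other_max`` (%). All comparisons are inclusive.
    The returned frame keeps one row per passing (probe, direction) with a
    ``pass`` column set True; an empty result is permitted.
    """
    dirs = set(_resolve_directions(directions))
    suffix = {SURVIVOR: "survivor", NON_SURVIVOR: "nonsurvivor"}
    verdicts = np.zeros(len(table), dtype=bool)
    for i, row in enumerate(table.itertuples(index=False)):
        d = row.direction
        if d not in dirs:
            continue
        elev, other = suffix[d], suffix[_OTHER[d]]
        pfc = getattr(row, f"pfc_{elev}")
        verdicts[i] = (
            np.isfinite(pfc)
            and pfc >= pfc_min
            and getattr(row, f"pen_freq_{elev}") >= pen_elevated_min
            and getattr(row, f"pen_freq_{other}") <= pen_other_max
        )
    out = table.loc[verdicts].copy()
    out["pass"] = True
    return out


@dataclass
class PenetranceResult:
    """Full table plus the passing probe set, as produced by :func:`run_pfc`."""

    table: pd.DataFrame
    passing: pd.DataFrame

    @property
    def probes(self) -> list[str]:
        return sorted(self.passing["probe"].unique())


def run_pfc(
    values: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 2.0,
    pfc_min: float = 2.0,
    pen_elevated_min: float = 10.0,
    pen_other_max: float = 10.0,
    directions: str = "both",
) -> PenetranceResult:
    """Convenience wrapper: IFC -> penetrance stats -> three-criterion filter."""
    table = penetrance_analysis(values, labels, threshold, directions)
    passing = pfc_filter(table, pfc_min, pen_elevated_min, pen_other_max, directions)
    return PenetranceResult(table=table, passing=passing)
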