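"""Synthetic immunome-array cohorts with planted prognostic autoantibody markers.

The simulator emulates a serum autoantibody protein-microarray study: ~1600
protein probes spotted in quadruplicate, positive-control probes, a cohort of
surgically resected patients labelled survivor / non-survivor, and survival
times whose hazard depends on how many planted markers a patient expresses.

Intensities are log-normal: each probe draws a probe-specific log-mean from a
hyperprior, each sample adds biological log-noise plus a sample-wide array
effect (what control-probe anchoring later removes), and replicate spots add
multiplicative technical noise around the sample-probe true intensity.

A planted marker elevates a random *penetrant* subset of one outcome group by
a fixed multiplier, mirroring the penetrance structure the fold-change filter
is designed to detect: only a fraction of the group carries the signal, but
carriers carry it strongly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

SURVIVOR = "survivor"
NON_SURVIVOR = "non-survivor"
OUTCOMES = (SURVIVOR, NON_SURVIVOR)

#: Administrative follow-up horizon (days); survivors are event-free at their
#: follow-up time, drawn around this horizon.
DEFAULT_HORIZON = 1825.0

ANNOTATION_COLUMNS = [
    "sample_id",
    "outcome",
    "survival_time",
    "event",
    "age",
    "gender",
    "histology",
    "stage",
    "nodal_status",
    "lymphovascular_invasion",
    "adjuvant_chemotherapy",
    "cohort",
]


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


class SplitError(ValueError):
    """Raised when a stratified split cannot be formed."""


@dataclass(frozen=True)
class PlantedMarker:
    """A probe elevated in a penetrant subset of one outcome group.

    Parameters
    ----------
    probe : probe identifier (e.g. ``"P0007"``).
    group : outcome group carrying the elevation.
    effect : multiplicative elevation applied to penetrant carriers, >= 1.
    penetrance : fraction of the group that carries the elevation, in [0, 1].
    """

    probe: str
    group: str = NON_SURVIVOR
    effect: float = 4.0
    penetrance: float = 0.6

    def __post_init__(self) -> None:
        if self.group not in OUTCOMES:
            raise ConfigurationError(f"unknown outcome group {self.group!r}")
        if not self.effect >= 1.0:
            raise ConfigurationError("effect multiplier must be >= 1")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigurationError("penetrance fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the immunome-array study design: 157 patients
    (92 survivors, 65 non-survivors), 1627 analyte probes in quadruplicate
    plus positive-control probes, a 5-year follow-up horizon and
    non-survivor deaths concentrated in the first post-operative year.
    """

    n_samples: int = 157
    n_probes: int = 1627
    n_replicates: int = 4
    n_control_probes: int = 8
    group_sizes: tuple[int, int] = (92, 65)  # (survivors, non-survivors)
    planted_markers: tuple[PlantedMarker, ...] = ()
    background_log_mean: float = 6.0
    background_log_sd: float = 0.5
    probe_log_mean_sd: float = 0.8
    replicate_log_sd: float = 0.1
    array_effect_log_sd: float = 0.15
    control_log_mean: float = 8.0
    control_log_sd: float = 0.2
    baseline_hazard: float = math.log(2) / 365.0  # day^-1; median death ~1 y
    hazard_link: float = 0.3
    censoring_rate: float = 0.1
    follow_up_horizon: float = DEFAULT_HORIZON
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_samples:
            raise ConfigurationError(
                f"group sizes {self.group_sizes} do not sum to "
                f"n_samples={self.n_samples}"
            )
        if self.n_probes < 1 or self.n_replicates < 1 or self.n_control_probes < 0:
            raise ConfigurationError("counts must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1]")
        probe_ids = set(analyte_probe_ids(self.n_probes))
        for m in self.planted_markers:
            if m.probe not in probe_ids:
                raise ConfigurationError(f"planted probe {m.probe!r} not on array")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_markers"] = [asdict(m) for m in self.planted_markers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["planted_markers"] = tuple(
            PlantedMarker(**m) for m in d.get("planted_markers", ())
        )
        d["group_sizes"] = tuple(d["group_sizes"])
        return cls(**d)


def analyte_probe_ids(n_probes: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n_probes)]


def control_probe_ids(n_control: int) -> list[str]:
    return [f"CTRL{i:02d}" for i in range(n_control)]


@dataclass
class RFUMatrix:
    """Replicate-level relative-fluorescence-unit matrix.

    ``values`` is samples x (probe, replicate) with a two-level column index;
    all intensities are strictly positive. Control probes are disjoint from
    analyte probes and carry no biology.
    """

    values: pd.DataFrame
    control_probes: frozenset[str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("RFU intensities must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())

    @property
    def analyte_probes(self) -> list[str]:
        return [p for p in self.probe_ids if p not in self.control_probes]

    @property
    def n_replicates(self) -> int:
        counts = self.values.columns.get_level_values(0).value_counts()
        return int(counts.iloc[0])

    def to_tsv(self, path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{p}@{r}" for p, r in self.values.columns]
        flat.index.name = "sample_id"
        flat.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, control_probes) -> "RFUMatrix":
        flat = pd.read_csv(path, sep="\t", index_col="sample_id")
        cols = pd.MultiIndex.from_tuples(
            [(c.rsplit("@", 1)[0], int(c.rsplit("@", 1)[1])) for c in flat.columns],
            names=["probe", "replicate"],
        )
        flat.columns = cols
        return cls(values=flat, control_probes=frozenset(control_probes))


def simulate_cohort(config: SimulationConfig) -> tuple[RFUMatrix, pd.DataFrame]:
    """Simulate one cohort; same config (incl. seed) gives identical output.

    Returns the replicate-level ``RFUMatrix`` and a sample annotation table
    (one row per sample, columns :data:`ANNOTATION_COLUMNS` minus ``cohort``,
    which :func:`stratified_split` assigns).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:03d}" for i in range(n)]
    analytes = analyte_probe_ids(config.n_probes)
    controls = control_probe_ids(config.n_control_probes)

    n_surv, n_nonsurv = config.group_sizes
    outcome = np.array([SURVIVOR] * n_surv + [NON_SURVIVOR] * n_nonsurv)
    outcome = outcome[rng.permutation(n)]

    # analyte intensities: probe hyperprior + sample biological noise
    probe_mu = rng.normal(
        config.background_log_mean, config.probe_log_mean_sd, config.n_probes
    )
    log_true = probe_mu[None, :] + rng.normal(
        0.0, config.background_log_sd, (n, config.n_probes)
    )
    true = np.exp(log_true)

    # planted penetrant elevations and per-sample marker burden
    burden = np.zeros(n, dtype=int)
    probe_index = {p: j for j, p in enumerate(analytes)}
    for m in config.planted_markers:
        group_idx = np.flatnonzero(outcome == m.group)
        k = int(round(m.penetrance * group_idx.size))
        carriers = rng.choice(group_idx, size=k, replace=False)
        true[carriers, probe_index[m.probe]] *= m.effect
        burden[carriers] += 1

    ctrl_true = np.exp(
        rng.normal(config.control_log_mean, config.control_log_sd, len(controls))
    )[None, :].repeat(n, axis=0)

    array_effect = np.exp(rng.normal(0.0, config.array_effect_log_sd, n))
    all_true = np.concatenate([true, ctrl_true], axis=1) * array_effect[:, None]
    probes = analytes + controls

    reps = all_true[:, :, None] * np.exp(
        rng.normal(0.0, config.replicate_log_sd, (n, len(probes), config.n_replicates))
    )
    cols = pd.MultiIndex.from_product(
        [probes, range(config.n_replicates)], names=["probe", "replicate"]
    )
    values = pd.DataFrame(
        reps.reshape(n, len(probes) * config.n_replicates),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=cols,
    )
    matrix = RFUMatrix(values=values, control_probes=frozenset(controls))

    annotation = _simulate_annotation(config, rng, sample_ids, outcome, burden)
    return matrix, annotation


def _simulate_annotation(config, rng, sample_ids, outcome, burden) -> pd.DataFrame:
    n = len(sample_ids)
    horizon = config.follow_up_horizon
    is_nonsurv = outcome == NON_SURVIVOR

    # Outcome labels are fixed by design (the study enrolls known survivor /
    # non-survivor counts), so event times are drawn conditional on outcome:
    # non-survivors die before the horizon with log-rate proportional to
    # planted-marker burden; survivors are event-free at follow-up.
    rate = config.baseline_hazard * np.exp(config.hazard_link * burden)
    u = rng.uniform(size=n)
    with np.errstate(divide="ignore"):
        t_event = -np.log1p(-u * (1.0 - np.exp(-rate * horizon))) / rate

    follow_up = rng.uniform(1195.0, 2555.0, size=n)
    lost_early = rng.uniform(size=n) < config.censoring_rate
    follow_up = np.where(lost_early, rng.uniform(180.0, 1195.0, size=n), follow_up)

    # day resolution with a 1-day floor: an extreme hazard can otherwise
    # round an event time to zero
    time = np.maximum(np.where(is_nonsurv, t_event, follow_up), 1.0)
    event = is_nonsurv.copy()

    age = np.clip(rng.normal(68.0, 8.0, n), 40.0, 90.0).round(1)
    gender = rng.choice(["male", "female"], size=n, p=[0.55, 0.45])
    histology = rng.choice(["adenocarcinoma", "squamous"], size=n, p=[0.55, 0.45])
    stage_probs = np.where(
        is_nonsurv[:, None], [[0.35, 0.35, 0.30]], [[0.60, 0.28, 0.12]]
    )
    stage = np.array(
        [rng.choice([1, 2, 3], p=p) for p in stage_probs]
    )
    nodal = (rng.uniform(size=n) < np.where(stage >= 2, 0.55, 0.15)).astype(int)
    lvi = rng.uniform(size=n) < np.where(is_nonsurv, 0.45, 0.25)
    chemo = rng.uniform(size=n) < np.where(stage >= 2, 0.6, 0.1)

    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "outcome": outcome,
            "survival_time": np.round(time, 1),
            "event": event,
            "age": age,
            "gender": gender,
            "histology": histology,
            "stage": stage,
            "nodal_status": nodal,
            "lymphovascular_invasion": lvi,
            "adjuvant_chemotherapy": chemo,
            # not part of the canonical annotation schema; kept for
            # simulator introspection (how many planted markers a sample
            # carries), dropped on serialization
            "marker_burden": burden,
        }
    ).set_index("sample_id")
    return ann


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(
    annotation: pd.DataFrame, train_fraction: float, seed: int = 0
) -> pd.Series:
    """Assign each sample to cohort 1 (training) or cohort 2 (validation).

    Per outcome group, the training count is round(group size x fraction),
    half rounded away from zero; if the per-group counts miss the overall
    target round(n x fraction), the residual is absorbed by the largest
    group. Assignment within a group is random given ``seed``.

    With 92 survivors, 65 non-survivors and fraction 111/157 this yields the
    65 + 46 = 111 training composition exactly.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SplitError("train_fraction must lie strictly between 0 and 1")
    if annotation["outcome"].isna().any():
        raise SplitError("outcome label missing for some samples")

    rng = np.random.default_rng(seed)
    groups = annotation.groupby("outcome", sort=True).groups
    sizes = {g: len(idx) for g, idx in groups.items()}
    for g, sz in sizes.items():
        if sz < 2:
            raise SplitError(f"group {g!r} has fewer than 2 samples")

    n_train = {g: _round_half_away(sz * train_fraction) for g, sz in sizes.items()}
    target = _round_half_away(len(annotation) * train_fraction)
    residual = target - sum(n_train.values())
    if residual != 0:
        largest = max(sizes, key=lambda g: (sizes[g], g))
        n_train[largest] = min(max(n_train[largest] + residual, 1), sizes[largest] - 1)

    cohort = pd.Series(2, index=annotation.index, name="cohort", dtype=int)
    for g in sorted(groups):
        idx = np.asarray(groups[g])
        chosen = rng.permutation(idx.size)[: n_train[g]]
        cohort.loc[idx[chosen]] = 1
    return cohort
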