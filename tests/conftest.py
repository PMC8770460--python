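import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import immunoprog as ip

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def gaussian_frame(rng, n, p, prefix="P"):
    """Samples x probes frame of standard normal values."""
    return pd.DataFrame(
        rng.normal(0.0, 1.0, (n, p)),
        columns=[f"{prefix}{j:04d}" for j in range(p)],
        index=[f"S{i:03d}" for i in range(n)],
    )


def outcome_series(y01, index):
    return pd.Series(
        np.where(np.asarray(y01).astype(bool), ip.NON_SURVIVOR, ip.SURVIVOR),
        index=index,
        name="outcome",
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """157-sample cohort with two planted markers, shared across tests."""
    markers = (
        ip.PlantedMarker("P0000", group=ip.NON_SURVIVOR, effect=4.0, penetrance=0.6),
        ip.PlantedMarker("P0001", group=ip.SURVIVOR, effect=3.0, penetrance=0.5),
    )
    config = ip.SimulationConfig(
        n_samples=157,
        n_probes=120,
        n_control_probes=6,
        group_sizes=(92, 65),
        planted_markers=markers,
        seed=11,
    )
    matrix, annotation = ip.simulate_cohort(config)
    annotation["cohort"] = ip.stratified_split(annotation, 111 / 157, seed=11)
    return config, matrix, annotation


@pytest.fixture(scope="session")
def normalized_cohort(planted_cohort):
    _, matrix, annotation = planted_cohort
    norm = ip.composite_normalize(ip.aggregate_replicates(matrix))
    return norm.analyte_values(), annotation
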