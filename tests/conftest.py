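import logging

import numpy as np
import pandas as pd
import pytest

import rccimmune as ri
from rccimmune.expression_processing import RawCountMatrix

logging.disable(logging.WARNING)


def make_raw(counts: dict[str, list[float]], classes: dict[str, str]) -> RawCountMatrix:
    """Small hand-built RawCountMatrix; counts maps probe -> per-sample values."""
    frame = pd.DataFrame(counts).T
    frame.columns = [f"s{i}" for i in range(frame.shape[1])]
    return RawCountMatrix(frame.astype(float), pd.Series(classes))


@pytest.fixture(scope="session")
def default_panel():
    return ri.build_panel(ri.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Compact simulated cohort shared by read-only tests."""
    cfg = ri.SimulationConfig(
        n_samples=40, n_endogenous=120, n_housekeeping=8, seed=5,
        effect_map={"T-cell": -1.0},
    )
    panel, cohort = ri.simulate_cohort(cfg)
    return cfg, panel, cohort


@pytest.fixture(scope="session")
def normalized_small(small_cohort):
    _, panel, cohort = small_cohort
    floored = ri.background_floor(cohort.raw_counts)
    normed, _ = ri.positive_control_normalize(floored)
    return panel, cohort, ri.log2_quantile_normalize(normed)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
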