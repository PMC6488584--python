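import numpy as np
import pandas as pd
import pytest

from cortexdyn.activity import LongitudinalTable
from cortexdyn.synthetic import SimulationConfig, simulate_traces


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by detection-level tests.

    Rates are kept within the detector's resolving range (the full-trace-SD
    threshold saturates for isolated events above ~2.3 transients/min);
    recovery under the full default rate distribution is exercised at scale
    in the acceptance tests.
    """
    cfg = SimulationConfig(n_cells=40, n_sessions=2, duration_s=300, seed=11,
                           category_weights=(0.25, 0.35, 0.40, 0.0),
                           rate_ranges=((0, 0), (0.05, 0.5), (0.5, 2.0), (4, 5)))
    traces, gt = simulate_traces(cfg)
    return cfg, traces, gt


@pytest.fixture
def freq_table():
    """Hand-built longitudinal frequency table with known structure."""
    freq = pd.DataFrame(
        {
            "s0": [0.0, 0.2, 1.0, 5.0],
            "s1": [0.8, 0.0, 1.5, 4.5],
            "s2": [0.9, 0.1, 0.0, 6.0],
        },
        index=["cA", "cB", "cC", "cD"],
    )
    return LongitudinalTable(frequency=freq)
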