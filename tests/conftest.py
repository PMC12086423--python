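import numpy as np
import pandas as pd
import pytest

from cgmstaging import CohortConfig, GlucoseTrace, TrueGlycemicState, generate_trace


def make_trace(values, start="2023-01-01 00:00:00", interval=5, pid="P1", sid="1",
               lot="A", flags=None):
    """Build a uniform-cadence trace from a list of glucose values."""
    values = np.asarray(values, dtype=float)
    times = pd.date_range(start, periods=len(values), freq=f"{interval}min")
    return GlucoseTrace(pid, sid, lot, times, values, flags=flags)


@pytest.fixture
def control_state():
    return TrueGlycemicState(baseline=109.0, excursion_scale=1.0, group="control")


@pytest.fixture
def default_config():
    return CohortConfig()


@pytest.fixture
def random_trace_factory(default_config, control_state):
    """Physiologic synthetic traces with varying seeds."""

    def make(seed, duration_hours=120.0, **kwargs):
        return generate_trace(
            control_state, default_config, duration_hours, seed, **kwargs
        )

    return make
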