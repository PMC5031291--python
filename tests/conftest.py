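import logging

import numpy as np
import pytest

from cellphenofit.data_io import Condition, ExperimentDataset, ReplicateSeries
from cellphenofit.fitting import AggregatedSeries
from cellphenofit.growth_models import simulate_model


@pytest.fixture(autouse=True)
def _quiet_weight_warnings(caplog):
    # the sigma-floor warning fires constantly on synthetic single-sd data
    logging.getLogger("cellphenofit.fitting").setLevel(logging.ERROR)
    yield


def noiseless_series(model_name: str, truth: dict, times) -> dict:
    """AggregatedSeries for each observable of a model, from exact simulation."""
    times = np.asarray(times, float)
    traj = simulate_model(model_name, truth, times)
    return {
        obs: AggregatedSeries(obs, times, vals, np.full(times.size, np.nan),
                              np.ones(times.size, dtype=int))
        for obs, vals in traj.values.items()
    }


def make_small_dataset() -> ExperimentDataset:
    """One condition, Live only, 4 times x 3 replicates of exponential growth."""
    rng = np.random.default_rng(42)
    times = np.array([0.0, 24.0, 48.0, 72.0])
    truth = 500.0 * np.exp(0.03 * times)
    cond = Condition("control", {"media": "standard"})
    for i in range(3):
        counts = truth * (1 + 0.03 * rng.standard_normal(times.size))
        cond.replicates.setdefault("Live", []).append(
            ReplicateSeries(times, counts, replicate_id=f"r{i + 1}")
        )
    return ExperimentDataset(
        conditions=[cond],
        metadata={"cell_line_name": "TESTLINE", "media": "standard",
                  "notes": "synthetic fixture", "time_unit": "h"},
        user_info={"name": "Test User", "contact": "test@example.org"},
    )


@pytest.fixture
def small_dataset() -> ExperimentDataset:
    return make_small_dataset()
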