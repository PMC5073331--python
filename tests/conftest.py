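import numpy as np
import pytest
from hypothesis import settings

from meanet import SimulationConfig, SpikeTrainSet, simulate_culture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_trainset(trains: dict[int, list[float]], duration: float,
                  **meta) -> SpikeTrainSet:
    return SpikeTrainSet(
        trains={eid: np.asarray(t, dtype=float) for eid, t in trains.items()},
        duration=duration, **meta)


@pytest.fixture(scope="session")
def bursting_culture() -> SpikeTrainSet:
    """A 300 s culture with clear, well-separated network bursts."""
    cfg = SimulationConfig(seed=42, duration=300.0, background_rate=0.2,
                           burst_ibi_mean=10.0, burst_ibi_cv=0.4)
    return simulate_culture(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
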