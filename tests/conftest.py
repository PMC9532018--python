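import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spikecollide as sc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def probe():
    return sc.make_probe()


@pytest.fixture(scope="session")
def templates(probe):
    return sc.synthesize_templates(probe, n_units=20, seed=7)


@pytest.fixture(scope="session")
def similarity(templates):
    return sc.cosine_similarity(templates)


@pytest.fixture(scope="session")
def correlated_trains():
    """300 s of 20 correlated units at 10 Hz, 20% correlation."""
    return sc.generate_correlated(
        n_units=20, rate=10.0, correlation=0.2, duration=300.0, seed=11
    )


def toy_trains(times_per_unit: dict, duration: float) -> sc.SpikeTrainSet:
    """Build a SpikeTrainSet from a {unit: times} dict of lists."""
    return sc.SpikeTrainSet(
        unit_ids=np.array(sorted(times_per_unit)),
        times={u: np.asarray(t, dtype=float) for u, t in times_per_unit.items()},
        duration=duration,
    )


@pytest.fixture
def make_trains():
    return toy_trains
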