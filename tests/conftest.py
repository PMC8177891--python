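import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spinefc as sfc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry() -> sfc.ArrayGeometry:
    return sfc.default_geometry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_train(geometry, unit_id, electrode_id, times) -> sfc.SpikeTrain:
    return sfc.SpikeTrain(sfc.make_unit(unit_id, electrode_id, geometry), times)


@pytest.fixture()
def small_trial(geometry) -> sfc.Trial:
    """Five hand-built units on assorted electrodes, 10 s trial."""
    rng = np.random.default_rng(7)
    trains = [
        make_train(geometry, f"u{i}", eid,
                   np.sort(rng.uniform(0, 10_000, size=60)))
        for i, eid in enumerate([1, 5, 9, 14, 20])
    ]
    trial = sfc.Trial("small", 10.0, geometry, trains)
    trial.validate()
    return trial


def poisson_train(geometry, unit_id, electrode_id, rate_hz, duration_s, seed):
    unit = sfc.make_unit(unit_id, electrode_id, geometry)
    return sfc.simulate_baseline(unit, rate_hz, duration_s, 2.0, seed)
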