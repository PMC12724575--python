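import numpy as np
import pytest
from hypothesis import settings

import velozones as vz

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def four_state_model(means=(1.0, 3.0, 5.5, 8.0), sd=0.3, dwell=4.0, **kw) -> vz.LocomotionModel:
    n = len(means)
    return vz.LocomotionModel(
        state_means=np.asarray(means, float),
        state_sds=sd,
        dwell_mean_s=dwell,
        transition_weights=1.0 - np.eye(n),
        **kw,
    )


@pytest.fixture(scope="session")
def model4():
    """Well-separated four-state model (gaps >= 4 within-state SDs)."""
    return four_state_model()


@pytest.fixture(scope="session")
def trace4(model4):
    """One 20-minute trace from the four-state model."""
    return vz.simulate_trace(model4, 1200.0, seed=11)


@pytest.fixture(scope="session")
def cohort4(model4):
    """Twenty 20-minute traces, the stage-1/stage-2 study condition."""
    return vz.simulate_cohort(model4, 20, 1200.0, seed=11)


def constant_trace(v: float, n: int, hz: float = 10.0, sex: str = "other") -> vz.VelocityTrace:
    return vz.VelocityTrace(
        player_id="p", match_id="m", sex=sex, sample_hz=hz,
        times=np.arange(n) / hz, velocities=np.full(n, float(v)),
    )
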