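import numpy as np
import pytest

from imep.scales import published_scales
from imep.synthetic import Demographics, GeneratorConfig, generate_cohort
from imep.types import MarkerTrack, ParticipantProfile, PlateTrial


@pytest.fixture(scope="session")
def scales():
    return published_scales()


@pytest.fixture
def girl():
    """Profile at the derivation cohort's female means."""
    return ParticipantProfile(
        nickname="ana", sex="female", age=7.23, foot_size=32.48, leg_length=67.28,
        height=1.27, weight=25.91,
    )


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(n=75, seed=1))


@pytest.fixture
def static_trial():
    """Constant quiet-standing load: COP fixed at (2, 5) cm, 16 s at 250 Hz."""
    n = 4000
    fz = np.full(n, 500.0)
    return PlateTrial(
        participant="ana", test_type="SLB", eyes="open", support_foot="right",
        sampling_rate=250.0,
        fx=np.zeros(n), fy=np.zeros(n), fz=fz,
        mx=0.05 * fz, my=-0.02 * fz, mz=np.zeros(n),
    )


def make_track(x, y, marker="umbilicus"):
    return MarkerTrack(marker=marker, x=np.asarray(x, float), y=np.asarray(y, float))
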