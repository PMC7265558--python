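import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iolpost import EXAMPLE_CONSTANTS, EyeBiometry

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def constants():
    return EXAMPLE_CONSTANTS


@pytest.fixture
def mean_eye():
    """Eye at the calibration-group mean biometry."""
    return EyeBiometry(
        axial_length=28.08, acd=3.63, k_tcrp_4mm=39.24, k_trp_4mm=39.13, eye_id="mean"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sample_valid_states(rng, n, constants):
    """Random valid optical states: (D_c, P, AL mm, ELP mm, target SE)."""
    al = rng.uniform(22.0, 32.0, n)
    acd = rng.uniform(2.8, 4.4, n)
    from iolpost.haigis import elp_mm

    d = np.asarray(elp_mm(acd, al, constants), dtype=float)
    dc = rng.uniform(32.0, 50.0, n)
    p = rng.uniform(5.0, 30.0, n)
    target = rng.uniform(-3.0, 1.0, n)
    assert np.all((d > 0) & (d < al))
    return dc, p, al, d, target
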