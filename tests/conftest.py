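import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube():
    """Tiny calibrated cube: 4x5 pixels, 12 bands, sloped 'seed' block."""
    import hyperseed as hs

    wl = hs.wavelength_axis(12, (450.0, 950.0))
    refl = np.full((4, 5, 12), 0.9)
    ramp = np.linspace(0.2, 0.6, 12)
    refl[1:3, 1:3, :] = ramp
    return hs.HyperCube(reflectance=refl, wavelengths_nm=wl)
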