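import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from musedecode import headmodel as hm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sensors():
    return hm.standard_sensor_array()


@pytest.fixture(scope="session")
def coarse_leadfield(sensors):
    """Three-shell sphere on a coarse 30 mm grid (fast; 5 points per axis)."""
    return hm.build_spherical_leadfield(sensors, grid_spacing_mm=30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ar2_sources(rng, n=5, T=6000, fs=100.0, freqs=None, r=0.97):
    """Resonant AR(2) sources at distinct centre frequencies.

    Distinct resonances give each source a distinct lagged-autocovariance
    signature, which is what makes the mixture identifiable from second-order
    statistics alone.
    """
    from scipy import signal

    freqs = np.linspace(4, 36, n) if freqs is None else freqs
    S = np.empty((n, T))
    for i, f in enumerate(freqs):
        a1 = 2 * r * np.cos(2 * np.pi * f / fs)
        a2 = -r * r
        e = rng.standard_normal(T + 200)
        x = signal.lfilter([1.0], [1.0, -a1, -a2], e)[200:]
        S[i] = x / x.std()
    return S
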