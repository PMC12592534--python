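import numpy as np
import pytest

from axodiff import geometry, synthesize


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def constant_profile():
    """Uniform tube: 50 um at dl = 0.1, area pi/4."""
    l = np.arange(0, 50, 0.1)
    return geometry.AxonProfile(l, np.full(l.size, np.pi * 0.25))


def make_cosine_profile(eps=0.6, wavelength=20.0, length=300.0, dl=0.1):
    """alpha = 1 + eps cos(2 pi l / wavelength); tortuosity 1/sqrt(1-eps^2)."""
    l = np.arange(0, length, dl)
    return geometry.AxonProfile(l, 1.0 + eps * np.cos(2 * np.pi * l / wavelength))


@pytest.fixture()
def cosine_profile():
    return make_cosine_profile()


@pytest.fixture()
def small_bead_profile():
    """Short strongly beaded profile, small enough for the exact solver."""
    params = synthesize.BeadModelParams(
        bead_amplitude=2.5, bead_width=3.0, mean_spacing=3.0, sd_spacing=3.6,
        length=60.0, seed=3,
    )
    return synthesize.generate_bead_profile(params)
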