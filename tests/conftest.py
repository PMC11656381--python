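import numpy as np
import pytest

from specdecon import Spectrum
from specdecon.profiles import ProfileParams
from specdecon.synth import GroundTruth, make_spectrum


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def ramp_spectrum():
    x = np.linspace(0.0, 10.0, 101)
    return Spectrum(x, 2.0 + 0.5 * x)


@pytest.fixture
def three_gaussians():
    """Noiseless sum of three well-separated Gaussians on a 2000-point
    uniform grid, with its ground truth."""
    comps = (
        ProfileParams("gaussian", 25.0, 1.0, sigma=2.0),
        ProfileParams("gaussian", 50.0, 0.7, sigma=2.5),
        ProfileParams("gaussian", 75.0, 0.9, sigma=1.8),
    )
    gt = GroundTruth(components=comps)
    s, gt = make_spectrum(gt, 0.0, 100.0, 2000)
    return s, gt


def single_gaussian_spectrum(center=50.0, amplitude=1.0, sigma=3.0,
                             n=1001, span=(0.0, 100.0)):
    gt = GroundTruth(components=(
        ProfileParams("gaussian", center, amplitude, sigma=sigma),))
    s, _ = make_spectrum(gt, span[0], span[1], n)
    return s
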