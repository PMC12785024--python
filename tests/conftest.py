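import numpy as np
import pytest

from voigttrack.lineshape import VoigtComponent, eval_voigt
from voigttrack.spectra import Spectrum


def make_band_spectrum(components, grid, baseline=(0.0, 0.0), noise_sd=0.0,
                       seed=0, nu_ref=None):
    """Sum of Voigt components + linear baseline + optional white noise."""
    grid = np.asarray(grid, dtype=float)
    if nu_ref is None:
        nu_ref = 0.5 * (grid[0] + grid[-1])
    y = baseline[0] + baseline[1] * (grid - nu_ref)
    for c in components:
        y = y + eval_voigt(grid, c)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, grid.size)
    return Spectrum(grid, y)


@pytest.fixture
def band_spectrum_factory():
    return make_band_spectrum


@pytest.fixture
def single_voigt_spectrum():
    """Noiseless single Voigt on a kinetic-resolution grid, with baseline."""
    grid = 1000.0 + 0.5 * np.arange(301)  # 1000-1150 cm^-1
    comp = VoigtComponent(1.0, 1077.0, 4.0, 6.0)
    return make_band_spectrum([comp], grid, baseline=(0.01, 1e-5)), comp
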