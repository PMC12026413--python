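import numpy as np
import pytest

import fidsim as fs


@pytest.fixture(scope="session")
def grid():
    """The standing acquisition condition: 2048 points, 2000 Hz, 3 T 1H."""
    return fs.build_grid(2048, 2000.0, 127.7, 4.65)


@pytest.fixture(scope="session")
def toy_basis(grid):
    """Three-singlet toy brain basis (NAA 2.01 / Cr 3.03 / Cho 3.22 ppm)."""
    return fs.toy_brain_basis(grid)


@pytest.fixture(scope="session")
def naa_fid(toy_basis):
    return toy_basis["NAA"].fid


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def measure_fwhm_hz(real_spectrum, hz_per_bin):
    """Full width at half max of a real spectrum, with the half-level
    crossings located by linear interpolation between bins."""
    real = np.asarray(real_spectrum, dtype=float)
    k = int(real.argmax())
    half = real[k] / 2.0
    i = k
    while real[i] > half:
        i -= 1
    left = i + (half - real[i]) / (real[i + 1] - real[i])
    j = k
    while real[j] > half:
        j += 1
    right = j - (half - real[j]) / (real[j - 1] - real[j])
    return (right - left) * hz_per_bin
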