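"""Global acquisition artifacts: phase offsets, eddy currents, noise, SNR.

Phase conventions
-----------------
Zero-order phase is applied in the time domain as ``exp(-1j*phi0*pi/180)``;
first-order phase in the frequency domain as
``exp(-1j*phi1*(ppm - ppm_ref)*pi/180)``, pivoting exactly at ``ppm_ref``
(the water reference, 4.65 ppm by default).  First-order eddy currents follow
the two-parameter model ``exp(-1j*phi(t))`` with
``phi(t) = 2*pi*A0*t*exp(-t/tc0)``: a time constant much longer than the
acquisition reduces to a global frequency shift of A0 Hz, a short one to a
transient lineshape distortion.

SNR definition
--------------
Spectral SNR is the maximum peak height of the real spectral component
divided by one standard deviation of the noise.  ``add_noise`` converts a
requested linear SNR into a frequency-domain noise SD
``sigma = ref_height / snr0`` and draws complex Gaussian noise in the time
domain with per-channel SD ``sigma / sqrt(n)``, which the package FFT maps
back to exactly ``sigma`` per spectral channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "GlobalArtifactParams",
    "apply_phase0",
    "apply_phase1",
    "apply_eddy",
    "add_noise",
    "measure_snr",
]


@dataclass
class GlobalArtifactParams:
    """One spectrum's global artifact parameters."""

    phi0: float = 0.0  # degrees
    phi1: float = 0.0  # degrees per ppm
    ppm_ref: float = 4.65
    ec_amplitude: float = 0.0  # A0, Hz
    ec_timeconstant: float = 0.1  # tc0, seconds
    snr0: float = np.inf  # linear SNR; inf disables noise
    noise_correlated: bool = False

    def __post_init__(self) -> None:
        if self.ec_amplitude != 0.0 and self.ec_timeconstant <= 0:
            raise ValueError("ec_timeconstant must be > 0 when ec_amplitude != 0")
        if not self.snr0 > 0:
            raise ValueError(f"snr0 must be positive, got {self.snr0}")


def apply_phase0(fid: np.ndarray, phi0: float) -> np.ndarray:
    """Zero-order phase: global multiplication by exp(-1j*phi0*pi/180)."""
    if not np.isfinite(phi0):
        raise ValueError(f"phi0 must be finite, got {phi0}")
    return np.asarray(fid) * np.exp(-1j * np.deg2rad(phi0))


def apply_phase1(
    spectrum: np.ndarray, phi1: float, ppm_axis: np.ndarray, ppm_ref: float = 4.65
) -> np.ndarray:
    """First-order phase emanating from ppm_ref; the sample at ppm_ref is unchanged."""
    spectrum = np.asarray(spectrum)
    ppm_axis = np.asarray(ppm_axis)
    if spectrum.shape[-1] != ppm_axis.shape[-1]:
        raise ValueError("ppm axis length must match spectrum length")
    return spectrum * np.exp(-1j * np.deg2rad(phi1) * (ppm_axis - ppm_ref))


def apply_eddy(fid: np.ndarray, a0: float, tc0: float, t: np.ndarray) -> np.ndarray:
    """First-order eddy-current phase distortion."""
    if a0 != 0.0 and tc0 <= 0:
        raise ValueError(f"tc0 must be positive, got {tc0}")
    if a0 == 0.0:
        return np.asarray(fid).copy()
    t = np.asarray(t)
    phi = 2.0 * np.pi * a0 * t * np.exp(-t / tc0)
    return np.asarray(fid) * np.exp(-1j * phi)


def _quadrature(x: np.ndarray) -> np.ndarray:
    """90-degree (quadrature) partner of a real sequence via its analytic signal."""
    return np.imag(hilbert(np.asarray(x, dtype=float)))


def add_noise(
    fid: np.ndarray,
    snr0: float,
    ref_height: float,
    rng: np.random.Generator | int,
    correlated: bool = False,
) -> tuple[np.ndarray, float]:
    """Add complex Gaussian noise at a target spectral SNR.

    Returns the noisy FID and ``sigma``, the per-channel frequency-domain
    noise SD (``ref_height / snr0``).  ``snr0 = inf`` is the no-noise
    sentinel.  By default real and imaginary channels are independent draws;
    ``correlated=True`` draws one real vector and synthesizes the imaginary
    channel as its 90-degree quadrature partner.
    """
    fid = np.asarray(fid, dtype=complex)
    if not snr0 > 0:
        raise ValueError(f"snr0 must be positive, got {snr0}")
    if np.isinf(snr0):
        return fid.copy(), 0.0
    if not ref_height > 0:
        raise ValueError(f"ref_height must be positive, got {ref_height}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = fid.shape[-1]
    sigma = ref_height / snr0
    s_t = sigma / np.sqrt(n)  # time-domain per-channel SD under the FFT convention
    if correlated:
        re = rng.normal(0.0, s_t, size=n)
        noise = re + 1j * _quadrature(re)
    else:
        noise = rng.normal(0.0, s_t, size=n) + 1j * rng.normal(0.0, s_t, size=n)
    return fid + noise, float(sigma)


def measure_snr(
    spectrum: np.ndarray,
    noise_region: slice | np.ndarray | None = None,
) -> float:
    """Spectral SNR: max real peak height over noise-region real-channel SD.

    ``noise_region`` selects signal-free samples (a slice or boolean/index
    array over the ascending-ppm axis); the default is the highest-ppm 10%
    of the axis, i.e. the last tenth of the samples.  A noiseless spectrum
    returns ``inf``.
    """
    real = np.asarray(spectrum).real
    n = real.shape[-1]
    if noise_region is None:
        noise_region = slice(n - max(1, n // 10), n)
    region = real[noise_region]
    if np.size(region) < 2:
        raise ValueError("noise region must contain at least two samples")
    sd = float(np.std(region))
    if sd == 0.0:
        return float(np.inf)
    return float(real.max() / sd)
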