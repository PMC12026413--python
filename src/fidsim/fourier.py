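"""The package's single FFT convention.

All modules (noise scaling, frequency-shift signs, phase pivots) reference one
fixed transform: ``to_spectrum`` maps a time-domain FID to a spectrum on the
grid's *ascending* ppm axis, oriented so that multiplying the FID by
``exp(-1j * 2*pi * f * t)`` displaces the spectrum toward *higher* ppm by
``f / carrier_frequency`` ppm.  The transform is the unnormalized FFT, so a
complex time-domain noise vector with per-channel standard deviation ``s``
produces frequency-domain channels with standard deviation ``s * sqrt(n)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["to_spectrum", "from_spectrum", "peak_ppm"]


def to_spectrum(fid: np.ndarray) -> np.ndarray:
    """Transform a FID to the spectrum on the ascending-ppm axis."""
    fid = np.asarray(fid)
    return np.fft.fftshift(np.fft.fft(fid, axis=-1), axes=-1)[..., ::-1]


def from_spectrum(spectrum: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`to_spectrum`."""
    spectrum = np.asarray(spectrum)
    return np.fft.ifft(np.fft.ifftshift(spectrum[..., ::-1], axes=-1), axis=-1)


def peak_ppm(fid: np.ndarray, grid, zero_fill: int = 8) -> float:
    """Locate the magnitude peak of a FID's spectrum, in ppm.

    Zero-filling by ``zero_fill`` interpolates the spectral axis so the peak
    can be located to a fraction of a raw spectral bin.
    """
    n = grid.n_points * int(zero_fill)
    padded = np.zeros(n, dtype=complex)
    padded[: grid.n_points] = fid
    spec = to_spectrum(padded)
    f = np.fft.fftshift(np.fft.fftfreq(n, d=grid.dwell_time))
    hz = -f[::-1]
    k = int(np.argmax(np.abs(spec)))
    return float(grid.ppm_ref + hz[k] / grid.carrier_frequency)
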