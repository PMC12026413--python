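"""Acquisition grid: shared time and chemical-shift axes.

Every simulated FID lives on one uniform time axis ``t[k] = k / spectral_width``
and every spectrum on the matching chemical-shift (ppm) axis.  The ppm axis is
stored ascending; plotting in the conventional orientation (high ppm on the
left) is a display concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionGrid", "build_grid"]


@dataclass(frozen=True)
class AcquisitionGrid:
    """Uniform acquisition grid for a single-voxel MRS experiment.

    Parameters
    ----------
    n_points : int
        Number of complex FID samples.
    spectral_width : float
        Receiver bandwidth in Hz; the dwell time is ``1 / spectral_width``.
    carrier_frequency : float
        Spectrometer frequency in MHz (e.g. 127.7 for 1H at 3 T).
    ppm_ref : float
        Chemical-shift reference of the carrier (water, 4.65 ppm by default).
    """

    n_points: int
    spectral_width: float
    carrier_frequency: float = 127.7
    ppm_ref: float = 4.65
    t: np.ndarray = field(init=False, repr=False, compare=False)
    ppm: np.ndarray = field(init=False, repr=False, compare=False)
    hz_offset: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = self.n_points
        if not (isinstance(n, (int, np.integer)) and n >= 2):
            raise ValueError(f"n_points must be an integer >= 2, got {n!r}")
        for name in ("spectral_width", "carrier_frequency"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if not np.isfinite(self.ppm_ref):
            raise ValueError(f"ppm_ref must be finite, got {self.ppm_ref!r}")
        t = np.arange(n) / self.spectral_width
        # Frequency-offset axis paired with the package FFT convention
        # (see fidsim.fourier): ascending, containing 0 exactly.
        f = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / self.spectral_width))
        hz = -f[::-1]
        ppm = self.ppm_ref + hz / self.carrier_frequency
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "hz_offset", hz)

    @property
    def dwell_time(self) -> float:
        return 1.0 / self.spectral_width

    @property
    def hz_per_bin(self) -> float:
        return self.spectral_width / self.n_points

    @property
    def ppm_per_bin(self) -> float:
        return self.hz_per_bin / self.carrier_frequency

    def ppm_to_hz(self, ppm: np.ndarray | float) -> np.ndarray | float:
        """Offset from ppm_ref in Hz for a position on the ppm axis."""
        return (np.asarray(ppm) - self.ppm_ref) * self.carrier_frequency

    def hz_to_ppm(self, hz: np.ndarray | float) -> np.ndarray | float:
        """Position on the ppm axis for an offset from the carrier in Hz."""
        return self.ppm_ref + np.asarray(hz) / self.carrier_frequency

    def compatible(self, other: "AcquisitionGrid") -> bool:
        return (
            self.n_points == other.n_points
            and self.spectral_width == other.spectral_width
            and self.carrier_frequency == other.carrier_frequency
            and self.ppm_ref == other.ppm_ref
        )


def build_grid(
    n_points: int,
    spectral_width: float,
    carrier_frequency: float = 127.7,
    ppm_ref: float = 4.65,
) -> AcquisitionGrid:
    """Construct an :class:`AcquisitionGrid`, validating all arguments."""
    return AcquisitionGrid(
        n_points=int(n_points),
        spectral_width=float(spectral_width),
        carrier_frequency=float(carrier_frequency),
        ppm_ref=float(ppm_ref),
    )
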