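"""Metabolite-level signal model: amplitudes, Voigt lineshape, frequency shifts.

The metabolite part of a simulated FID is the weighted sum over basis
functions, each scaled by its millimolar amplitude, broadened by a Voigt
lineshape (Lorentzian decay rate ``d`` in 1/s and Gaussian rate ``g`` in
1/s^2, applied as ``exp(-(d*t + g*t**2))``), modulated by the sub-voxel B0
phase factor, and shifted by its individual frequency offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import GROUP_METABOLITE, BasisSet

__all__ = ["MetaboliteParams", "apply_lineshape", "apply_freq_shift", "scale_and_sum"]


@dataclass
class MetaboliteParams:
    """Per-spectrum metabolite-level parameters.

    ``amplitudes`` are mM-equivalent scaling factors per basis name;
    ``lorentzian`` holds one decay rate (1/s) per basis name; the Gaussian
    rate (1/s^2) is one value shared by all metabolites with a second value
    for macromolecules/lipids; ``freq_shifts`` are per-name offsets in Hz
    applied on top of the group-level global shift.
    """

    amplitudes: dict[str, float]
    lorentzian: dict[str, float] = field(default_factory=dict)
    gaussian_metab: float = 0.0
    gaussian_mm: float = 0.0
    freq_shifts: dict[str, float] = field(default_factory=dict)
    global_shift_metab: float = 0.0
    global_shift_nuisance: float = 0.0

    def __post_init__(self) -> None:
        for name, m in self.amplitudes.items():
            if m < 0:
                raise ValueError(f"amplitude for {name!r} must be >= 0, got {m}")
        for name, d in self.lorentzian.items():
            if d < 0:
                raise ValueError(f"lorentzian rate for {name!r} must be >= 0, got {d}")
        if self.gaussian_metab < 0 or self.gaussian_mm < 0:
            raise ValueError("gaussian rates must be >= 0")

    def gaussian_for(self, group: str) -> float:
        return self.gaussian_metab if group == GROUP_METABOLITE else self.gaussian_mm


def apply_lineshape(fid: np.ndarray, d: float, g: float, t: np.ndarray) -> np.ndarray:
    """Voigt broadening: multiply by ``exp(-(d*t + g*t**2))``.

    ``g = 0`` gives a pure Lorentzian (spectral FWHM = d/pi Hz), ``d = 0`` a
    pure Gaussian.  Negative rates would grow the FID and are rejected.
    """
    if d < 0 or g < 0:
        raise ValueError(f"lineshape rates must be >= 0, got d={d}, g={g}")
    t = np.asarray(t)
    return np.asarray(fid) * np.exp(-(d * t + g * t**2))


def apply_freq_shift(fid: np.ndarray, delta_f: float, t: np.ndarray) -> np.ndarray:
    """Shift the spectrum by ``delta_f`` Hz (toward higher ppm for +delta_f).

    Implemented as multiplication by ``exp(-1j*2*pi*delta_f*t)``; the
    displacement direction is fixed by the package FFT convention.
    """
    if not np.isfinite(delta_f):
        raise ValueError(f"frequency shift must be finite, got {delta_f}")
    return np.asarray(fid) * np.exp(-2j * np.pi * delta_f * np.asarray(t))


def scale_and_sum(
    basis: BasisSet,
    params: MetaboliteParams,
    modulators: dict[str, np.ndarray] | np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the metabolite FID: scale, broaden, modulate, shift, sum.

    For each basis function the amplitude is applied first, then the Voigt
    lineshape and the B0 modulator, then the per-name frequency shift; the
    processed functions are summed and the metabolite-group global shift is
    applied to the sum (identical to shifting every term individually).
    ``modulators`` may be one shared complex sequence or a per-name mapping.
    """
    t = basis.grid.t
    total = np.zeros(basis.grid.n_points, dtype=complex)
    for fn in basis.functions:
        if fn.name not in params.amplitudes:
            raise KeyError(f"no amplitude for basis function {fn.name!r}")
        sig = params.amplitudes[fn.name] * fn.fid
        d = params.lorentzian.get(fn.name, 0.0)
        sig = apply_lineshape(sig, d, params.gaussian_for(fn.group), t)
        if modulators is not None:
            mod = modulators.get(fn.name) if isinstance(modulators, dict) else modulators
            if mod is not None:
                sig = sig * mod
        sig = apply_freq_shift(sig, params.freq_shifts.get(fn.name, 0.0), t)
        total += sig
    if params.global_shift_metab:
        total = apply_freq_shift(total, params.global_shift_metab, t)
    return total
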