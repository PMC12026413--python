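"""Metabolite basis sets: containers, HDF5 I/O, and a synthetic toy generator.

A basis set is an ordered collection of named complex time-domain basis
functions sharing one acquisition grid.  Each basis function represents the
signal from 1.0 mM of its metabolite, so concentration scaling factors can be
used directly as millimolar amplitudes.

Real basis sets come from density-matrix simulators (MARSS, FID-A, ...) and
are loaded from the HDF5 container written by :func:`write_basis`.  The
synthetic generator :func:`synth_toy_basis` builds exponentially-decaying
singlet/multiplet basis functions from a line list; it is the package's
standing test fixture and demo input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .fourier import to_spectrum
from .grid import AcquisitionGrid, build_grid

__all__ = [
    "BasisFunction",
    "BasisSet",
    "synth_toy_basis",
    "toy_brain_basis",
    "read_basis",
    "write_basis",
]

GROUP_METABOLITE = "metabolite"
GROUP_MACROMOLECULE = "macromolecule"
_GROUPS = (GROUP_METABOLITE, GROUP_MACROMOLECULE)


@dataclass
class BasisFunction:
    """One named complex time-domain basis function (1.0 mM equivalent)."""

    name: str
    fid: np.ndarray
    group: str = GROUP_METABOLITE
    nominal_concentration: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("basis function name must be non-empty")
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        self.fid = np.asarray(self.fid, dtype=complex)
        if self.fid.ndim != 1:
            raise ValueError(f"basis fid for {self.name!r} must be 1-D")


@dataclass
class BasisSet:
    """Ordered, uniquely-named basis functions on a shared grid."""

    grid: AcquisitionGrid
    functions: list[BasisFunction] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.functions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate basis names: {sorted(names)}")
        for f in self.functions:
            if len(f.fid) != self.grid.n_points:
                raise ValueError(
                    f"basis function {f.name!r} has length {len(f.fid)}, "
                    f"grid expects {self.grid.n_points}"
                )

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.functions]

    def __len__(self) -> int:
        return len(self.functions)

    def __getitem__(self, name: str) -> BasisFunction:
        for f in self.functions:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.functions)


def synth_toy_basis(
    lines: dict[str, list[tuple[float, float]]] | list[tuple[str, list[tuple[float, float]]]],
    t2_star: dict[str, float] | float,
    grid: AcquisitionGrid,
    groups: dict[str, str] | None = None,
    normalize: bool = True,
) -> BasisSet:
    """Build a synthetic basis set from per-metabolite line lists.

    Each line ``(ppm_position, relative_amplitude)`` contributes
    ``amplitude * exp(1j*2*pi*f_line*t) * exp(-t/t2_star)`` with ``f_line``
    the line's offset from ``ppm_ref`` in Hz under the package frequency
    convention, so the transformed spectrum peaks at the requested ppm.  With
    ``normalize=True`` each fid is scaled so its noiseless real spectral
    maximum is 1.0, making "one basis unit = 1.0 mM" numerically concrete.
    """
    if isinstance(lines, dict):
        lines = list(lines.items())
    groups = groups or {}
    lo, hi = grid.ppm.min(), grid.ppm.max()
    funcs = []
    for name, linelist in lines:
        tau = t2_star[name] if isinstance(t2_star, dict) else float(t2_star)
        if tau <= 0:
            raise ValueError(f"t2_star for {name!r} must be positive, got {tau!r}")
        fid = np.zeros(grid.n_points, dtype=complex)
        for ppm_pos, amp in linelist:
            if not (lo <= ppm_pos <= hi):
                raise ValueError(
                    f"line at {ppm_pos} ppm for {name!r} outside grid span "
                    f"[{lo:.3f}, {hi:.3f}] ppm"
                )
            # Sign convention: e^{-i 2 pi f t} moves a peak toward higher
            # ppm, hence a line *at* ppm p needs f_line = (ppm_ref - p)*f0.
            f_line = (grid.ppm_ref - ppm_pos) * grid.carrier_frequency
            fid += amp * np.exp(2j * np.pi * f_line * grid.t)
        fid *= np.exp(-grid.t / tau)
        if normalize and np.any(fid):
            peak = to_spectrum(fid).real.max()
            if peak > 0:
                fid /= peak
        funcs.append(BasisFunction(name=name, fid=fid, group=groups.get(name, GROUP_METABOLITE)))
    return BasisSet(grid=grid, functions=funcs)


def toy_brain_basis(grid: AcquisitionGrid | None = None, include_mm: bool = False) -> BasisSet:
    """Three-singlet toy brain basis (NAA 2.01, Cr 3.03, Cho 3.22 ppm).

    The standing demonstration/test condition: 2048 points at 2000 Hz on a
    3 T 1H grid unless another grid is given.  ``include_mm`` adds a broad
    macromolecule resonance at 0.91 ppm.
    """
    if grid is None:
        grid = build_grid(2048, 2000.0, 127.7, 4.65)
    lines: dict[str, list[tuple[float, float]]] = {
        "NAA": [(2.01, 1.0)],
        "Cr": [(3.03, 1.0)],
        "Cho": [(3.22, 1.0)],
    }
    t2 = {"NAA": 0.10, "Cr": 0.10, "Cho": 0.10}
    groups = {}
    if include_mm:
        lines["MM09"] = [(0.91, 1.0)]
        t2["MM09"] = 0.025
        groups["MM09"] = GROUP_MACROMOLECULE
    return synth_toy_basis(lines, t2, grid, groups=groups)


def write_basis(basis: BasisSet, path) -> None:
    """Write a basis set to an HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.attrs["n_points"] = basis.grid.n_points
        f.attrs["spectral_width_hz"] = basis.grid.spectral_width
        f.attrs["carrier_frequency_mhz"] = basis.grid.carrier_frequency
        f.attrs["ppm_ref"] = basis.grid.ppm_ref
        f.attrs["order"] = basis.names
        g = f.create_group("basis")
        for fn in basis.functions:
            d = g.create_dataset(fn.name + "/fid", data=fn.fid)
            d.attrs["group"] = fn.group
            d.attrs["nominal_concentration_mm"] = fn.nominal_concentration


def read_basis(path) -> BasisSet:
    """Read a basis set written by :func:`write_basis`, validating metadata."""
    with h5py.File(path, "r") as f:
        for key in ("n_points", "spectral_width_hz", "carrier_frequency_mhz", "ppm_ref"):
            if key not in f.attrs:
                raise ValueError(f"basis file {path} missing required metadata {key!r}")
        grid = build_grid(
            int(f.attrs["n_points"]),
            float(f.attrs["spectral_width_hz"]),
            float(f.attrs["carrier_frequency_mhz"]),
            float(f.attrs["ppm_ref"]),
        )
        order = [str(n) for n in f.attrs["order"]]
        funcs = []
        for name in order:
            ds = f[f"basis/{name}/fid"]
            fid = ds[()]
            if len(fid) != grid.n_points:
                raise ValueError(
                    f"basis function {name!r} has fid length {len(fid)}, "
                    f"expected n_points={grid.n_points}"
                )
            funcs.append(
                BasisFunction(
                    name=name,
                    fid=fid,
                    group=str(ds.attrs.get("group", GROUP_METABOLITE)),
                    nominal_concentration=float(ds.attrs.get("nominal_concentration_mm", 1.0)),
                )
            )
    return BasisSet(grid=grid, functions=funcs)
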