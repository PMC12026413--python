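"""Declarative JSON configuration for batch simulation runs.

A run config mirrors :class:`fidsim.pipeline.SamplingSpec`: per-parameter
distribution descriptors (``{"fixed": v}``, ``{"uniform": [lo, hi]}``,
``{"normal": [mu, sd]}``, ``{"clamped_normal": [mu, sd, lo, hi]}``),
component flags, the acquisition grid and the basis source.  Configs are
validated on load with errors naming the offending field, and the parsed
config is version-stamped into the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

from . import __version__
from .basis import BasisSet, read_basis, toy_brain_basis
from .grid import build_grid
from .nuisance import baseline_profile, residual_water_profile
from .pipeline import Dist, SamplingSpec
from .transients import CoilConfig

__all__ = ["load_config", "config_manifest", "example_config"]

_DIST_FIELDS = (
    "gaussian_metab",
    "gaussian_mm",
    "global_shift_metab",
    "global_shift_nuisance",
    "phi0",
    "phi1",
    "ec_amplitude",
    "ec_timeconstant",
    "snr",
    "b0_mu",
    "b0_delta",
    "baseline_scale",
    "water_scale",
)
_FLAG_FIELDS = (
    "noise_enabled",
    "noise_correlated",
    "baseline_enabled",
    "water_enabled",
    "phases_enabled",
    "eddy_enabled",
    "b0_enabled",
    "transients_enabled",
)


def _parse_dist(value, field: str) -> Dist:
    try:
        if isinstance(value, (int, float)):
            return Dist("fixed", (float(value),))
        return Dist.from_dict(value)
    except (ValueError, TypeError) as e:
        raise ValueError(f"config field {field!r}: {e}") from e


def _parse_per_name(value, field: str):
    if isinstance(value, dict) and not any(k in Dist._KINDS for k in value):
        return {name: _parse_dist(v, f"{field}[{name}]") for name, v in value.items()}
    return _parse_dist(value, field)


def load_config(path) -> tuple[SamplingSpec, BasisSet, dict]:
    """Load and validate a run config; returns (spec, basis, raw config)."""
    raw = json.loads(Path(path).read_text())
    if "amplitudes" not in raw:
        raise ValueError("config must define 'amplitudes' (one descriptor per metabolite)")

    basis_cfg = raw.get("basis", {"toy": True})
    if "path" in basis_cfg:
        basis = read_basis(basis_cfg["path"])
    else:
        g = raw.get(
            "grid",
            {"n_points": 2048, "spectral_width": 2000.0,
             "carrier_frequency": 127.7, "ppm_ref": 4.65},
        )
        grid = build_grid(
            g["n_points"], g["spectral_width"],
            g.get("carrier_frequency", 127.7), g.get("ppm_ref", 4.65),
        )
        basis = toy_brain_basis(grid, include_mm=basis_cfg.get("include_mm", False))

    kwargs: dict = {
        "amplitudes": {
            name: _parse_dist(v, f"amplitudes[{name}]")
            for name, v in raw["amplitudes"].items()
        }
    }
    unknown = set(raw["amplitudes"]) - set(basis.names)
    if unknown:
        raise ValueError(f"amplitudes reference unknown basis names: {sorted(unknown)}")
    missing = set(basis.names) - set(raw["amplitudes"])
    if missing:
        raise ValueError(f"amplitudes missing for basis names: {sorted(missing)}")
    for field in ("lorentzian", "freq_shift"):
        if field in raw:
            kwargs[field] = _parse_per_name(raw[field], field)
    for field in _DIST_FIELDS:
        if field in raw:
            kwargs[field] = _parse_dist(raw[field], field)
    for field in _FLAG_FIELDS:
        if field in raw:
            if not isinstance(raw[field], bool):
                raise ValueError(f"config field {field!r} must be a boolean")
            kwargs[field] = raw[field]
    if "b0_grid_shape" in raw:
        kwargs["b0_grid_shape"] = tuple(int(x) for x in raw["b0_grid_shape"])
    if "coil" in raw:
        kwargs["coil"] = CoilConfig(**raw["coil"])
    for field, default in (("baseline", baseline_profile()), ("water", residual_water_profile())):
        if field in raw:
            opts = dict(raw[field])
            if "ppm_span" in opts:
                opts["ppm_span"] = tuple(opts["ppm_span"])
            kwargs[field] = replace(default, **opts)
    if "tl" in raw:
        kwargs["tl"] = float(raw["tl"])
    if "zero_fill_len" in raw:
        kwargs["zero_fill_len"] = int(raw["zero_fill_len"])
    spec = SamplingSpec(**kwargs)
    return spec, basis, raw


def config_manifest(raw: dict, seed: int, n: int) -> dict:
    """Run manifest: seed, config hash and package version."""
    blob = json.dumps(raw, sort_keys=True).encode()
    return {
        "seed": int(seed),
        "n_spectra": int(n),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "fidsim_version": __version__,
        "config": raw,
    }


def example_config() -> dict:
    """A minimal runnable config for the built-in toy basis."""
    return {
        "grid": {"n_points": 2048, "spectral_width": 2000.0},
        "basis": {"toy": True},
        "amplitudes": {
            "NAA": {"uniform": [7.5, 17.0]},
            "Cr": {"uniform": [4.0, 11.5]},
            "Cho": {"uniform": [0.5, 2.5]},
        },
        "lorentzian": {"uniform": [2.0, 8.0]},
        "gaussian_metab": {"uniform": [0.0, 200.0]},
        "snr": {"fixed": 15.0},
        "noise_enabled": True,
        "phases_enabled": True,
        "phi0": {"uniform": [-20.0, 20.0]},
        "phi1": {"uniform": [-5.0, 5.0]},
        "baseline_enabled": True,
        "water_enabled": True,
        "b0_enabled": True,
        "b0_mu": {"uniform": [-10.0, 10.0]},
        "b0_delta": {"uniform": [0.0, 4.0]},
    }
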