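"""Semi-parametric baseline and residual-water generation.

The spectral baseline and the residual (imperfectly suppressed) water region
have no accepted physics-based model, so both are generated by the same
smoothed, bounded pseudo-random walk: a cumulative-sum random walk is
decomposed into a linear trend between the requested endpoint values plus
deltas, the deltas are renormalized to the bound width, the composed curve is
clipped to the bounds, and a uniform smoothing kernel (a fraction
``window_size`` of the curve length) is applied with reflective padding.
Broad smooth baselines and highly irregular residual-water profiles differ
only in their configuration (chiefly ``window_size``).

Walks are real curves on a ppm interval; ``make_complex_nuisance`` completes
them with the 90-degree quadrature (dispersion) partner — for a Lorentzian
absorption input this reproduces the closed-form dispersion curve — and
``resample_to_grid`` interpolates them onto the acquisition ppm axis, zero
outside the profile's span.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import hilbert

__all__ = [
    "WalkConfig",
    "NuisanceCurve",
    "bounded_smoothed_walk",
    "make_complex_nuisance",
    "resample_to_grid",
    "scale_nuisance",
    "baseline_profile",
    "residual_water_profile",
    "generate_nuisance",
]


@dataclass(frozen=True)
class WalkConfig:
    """Configuration of one bounded smoothed walk."""

    start: float = 0.0
    end: float = 0.0
    std: float = 1.0
    lower_bound: float = -1.0
    upper_bound: float = 1.0
    length: int = 256
    window_size: float = 0.15
    profile: str = "baseline"
    ppm_span: tuple[float, float] = (0.2, 4.2)
    scale: float = 0.25

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError(
                f"lower_bound must be < upper_bound, got "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )
        if not (0.0 < self.window_size <= 1.0):
            raise ValueError(f"window_size must be in (0, 1], got {self.window_size}")
        if self.length < 8:
            raise ValueError(f"length must be >= 8, got {self.length}")
        if self.std < 0:
            raise ValueError(f"std must be >= 0, got {self.std}")
        for name in ("start", "end"):
            v = getattr(self, name)
            if not (self.lower_bound <= v <= self.upper_bound):
                raise ValueError(f"{name}={v} outside bounds")
        if not self.ppm_span[0] < self.ppm_span[1]:
            raise ValueError(f"ppm_span must be increasing, got {self.ppm_span}")


@dataclass
class NuisanceCurve:
    """A complex baseline or residual-water contribution on the spectral axis."""

    values: np.ndarray
    kind: str
    ppm_span: tuple[float, float]
    ground_truth: bool = True


def bounded_smoothed_walk(cfg: WalkConfig, seed: int | np.random.Generator) -> np.ndarray:
    """Generate one smoothed, bounded pseudo-random walk.

    Deterministic for a given (cfg, seed); every sample lies within
    ``[lower_bound, upper_bound]``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bounds = cfg.upper_bound - cfg.lower_bound
    walk = np.cumsum(rng.normal(0.0, cfg.std, size=cfg.length))
    trend = np.linspace(cfg.start, cfg.end, cfg.length)
    # deltas are the walk's deviations from its own endpoint line, so the
    # start->end trend carries the endpoints and the deltas carry only noise
    deltas = walk - np.linspace(walk[0], walk[-1], cfg.length)
    spread = deltas.max() - deltas.min()
    # degenerate spread (std=0, or vanishingly small steps) -> no noise term
    with np.errstate(over="ignore"):
        ratio = bounds / spread if spread > 0 else np.inf
    if np.isfinite(ratio):
        deltas = deltas * ratio
    else:
        deltas = np.zeros_like(deltas)
    # conditional adjustment: clip the composed curve into the bounds
    curve = np.clip(trend + deltas, cfg.lower_bound, cfg.upper_bound)
    k = max(1, int(round(cfg.window_size * cfg.length)))
    if k > 1:
        padded = np.pad(curve, (k // 2, k - 1 - k // 2), mode="reflect")
        curve = np.convolve(padded, np.full(k, 1.0 / k), mode="valid")
    return curve


def make_complex_nuisance(real_curve: np.ndarray) -> np.ndarray:
    """Complete a real curve with its 90-degree quadrature partner.

    The imaginary channel is the quarter-cycle phase rotation of the real
    channel (transform, rotate, back-transform); applying the rotation twice
    negates the original curve.
    """
    x = np.asarray(real_curve, dtype=float)
    if x.size == 0:
        return x.astype(complex)
    return x + 1j * np.imag(hilbert(x))


def resample_to_grid(
    curve: np.ndarray,
    ppm_span: tuple[float, float],
    target_ppm_axis: np.ndarray,
) -> np.ndarray:
    """Interpolate a curve from its ppm span onto a target axis.

    The curve is assumed uniformly sampled over ``ppm_span`` (ascending);
    the result is zero outside the span.  Disjoint spans are rejected.
    """
    curve = np.asarray(curve)
    target = np.asarray(target_ppm_axis, dtype=float)
    lo, hi = ppm_span
    if hi <= target.min() or lo >= target.max():
        raise ValueError(
            f"curve span {ppm_span} does not overlap target axis "
            f"[{target.min():.3f}, {target.max():.3f}]"
        )
    src = np.linspace(lo, hi, len(curve))
    out = np.zeros(len(target), dtype=curve.dtype)
    inside = (target >= lo) & (target <= hi)
    if curve.dtype.kind == "c":
        f = interp1d(src, curve.real, kind="cubic"), interp1d(src, curve.imag, kind="cubic")
        out[inside] = f[0](target[inside]) + 1j * f[1](target[inside])
    else:
        out[inside] = interp1d(src, curve, kind="cubic")(target[inside])
    return out


def scale_nuisance(curve: np.ndarray, spectrum_max: float, scale: float) -> np.ndarray:
    """Scale a curve so its magnitude maximum equals ``scale * spectrum_max``."""
    curve = np.asarray(curve)
    if not spectrum_max > 0:
        raise ValueError(f"spectrum_max must be positive, got {spectrum_max}")
    if scale == 0:
        return np.zeros_like(curve)
    peak = np.abs(curve).max()
    if peak == 0:
        raise ValueError("cannot scale an all-zero curve to a nonzero magnitude")
    return curve * (scale * spectrum_max / peak)


def baseline_profile(**overrides) -> WalkConfig:
    """Default broad, smooth spectral-baseline profile (0.2-4.2 ppm)."""
    cfg = WalkConfig(
        profile="baseline", window_size=0.15, length=256, ppm_span=(0.2, 4.2), scale=0.25
    )
    return replace(cfg, **overrides) if overrides else cfg


def residual_water_profile(**overrides) -> WalkConfig:
    """Default irregular residual-water profile (4.2-5.1 ppm)."""
    cfg = WalkConfig(
        profile="residual_water", window_size=0.02, length=512, ppm_span=(4.2, 5.1), scale=1.0
    )
    return replace(cfg, **overrides) if overrides else cfg


def generate_nuisance(
    cfg: WalkConfig,
    target_ppm_axis: np.ndarray,
    spectrum_max: float,
    seed: int | np.random.Generator,
) -> NuisanceCurve:
    """Walk -> resample to the acquisition axis -> complex completion -> scale."""
    walk = bounded_smoothed_walk(cfg, seed)
    on_grid = resample_to_grid(walk, cfg.ppm_span, target_ppm_axis)
    values = make_complex_nuisance(on_grid)
    if np.abs(values).max() > 0:
        values = scale_nuisance(values, spectrum_max, cfg.scale)
    return NuisanceCurve(values=values, kind=cfg.profile, ppm_span=cfg.ppm_span)
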