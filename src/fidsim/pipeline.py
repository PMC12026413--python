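"""End-to-end simulation pipeline: sampling, assembly, post-processing, batching.

Assembly order for one spectrum (mirroring the acquisition chain):

1. each basis function is amplitude-scaled, Voigt-broadened, modulated by
   the sub-voxel B0 phase factor and frequency-shifted, then all are summed
   (plus the metabolite-group global shift);
2. baseline and residual-water contributions, generated on the spectral
   axis, enter the time-domain sum through the inverse transform;
3. noise is added at the requested spectral SNR — unless transients are
   enabled, in which case noise is deferred to the coil stage;
4. zero-order phase and eddy currents are applied in the time domain, the
   first-order phase in the frequency domain;
5. if transients are enabled, the coil operator produces C transients
   (sensitivities, drifts, per-transient noise) which are averaged back
   into the combined FID;
6. optional post-processing: apodization, zero-filling, FFT, crop/resample.

Every random draw is recorded in a :class:`ParameterSample`; a sample plus
the basis set reproduces its spectrum bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from .b0 import B0Params, b0_modulator, simulate_field_map
from .basis import BasisSet
from .artifacts import add_noise, apply_eddy, apply_phase0, apply_phase1
from .fourier import from_spectrum, to_spectrum
from .grid import AcquisitionGrid
from .lineshape import MetaboliteParams, scale_and_sum
from .nuisance import (
    NuisanceCurve,
    WalkConfig,
    baseline_profile,
    generate_nuisance,
    residual_water_profile,
)
from .transients import CoilConfig, TransientSet, combine_transients, make_transients

__all__ = [
    "Dist",
    "fixed",
    "uniform",
    "normal",
    "clamped_normal",
    "SamplingSpec",
    "ParameterSample",
    "SimulationResult",
    "SpectralDataset",
    "sample_parameters",
    "simulate_spectrum",
    "simulate_dataset",
    "apodize_zerofill_fft",
    "crop_resample",
]


# ---------------------------------------------------------------------------
# distribution descriptors

@dataclass(frozen=True)
class Dist:
    """A sampling-distribution descriptor for one scalar parameter."""

    kind: str
    args: tuple[float, ...]

    _KINDS = ("fixed", "uniform", "normal", "clamped_normal")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        n_expected = {"fixed": 1, "uniform": 2, "normal": 2, "clamped_normal": 4}
        if len(self.args) != n_expected[self.kind]:
            raise ValueError(f"{self.kind} takes {n_expected[self.kind]} arguments")
        if self.kind == "uniform" and self.args[0] > self.args[1]:
            raise ValueError(f"uniform requires lo <= hi, got {self.args}")
        if self.kind == "clamped_normal" and self.args[2] > self.args[3]:
            raise ValueError(f"clamped_normal requires lo <= hi, got {self.args}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.args[0])
        if self.kind == "uniform":
            return float(rng.uniform(self.args[0], self.args[1]))
        if self.kind == "normal":
            return float(rng.normal(self.args[0], self.args[1]))
        mu, sd, lo, hi = self.args
        return float(np.clip(rng.normal(mu, sd), lo, hi))

    def to_dict(self) -> dict:
        return {self.kind: list(self.args)}

    @classmethod
    def from_dict(cls, d: dict) -> "Dist":
        if len(d) != 1:
            raise ValueError(f"distribution descriptor must have one key, got {d}")
        kind, args = next(iter(d.items()))
        args = [args] if np.isscalar(args) else list(args)
        return cls(kind=kind, args=tuple(float(a) for a in args))


def fixed(v: float) -> Dist:
    return Dist("fixed", (float(v),))


def uniform(lo: float, hi: float) -> Dist:
    return Dist("uniform", (float(lo), float(hi)))


def normal(mu: float, sd: float) -> Dist:
    return Dist("normal", (float(mu), float(sd)))


def clamped_normal(mu: float, sd: float, lo: float, hi: float) -> Dist:
    return Dist("clamped_normal", (float(mu), float(sd), float(lo), float(hi)))


# ---------------------------------------------------------------------------
# sampling specification

@dataclass
class SamplingSpec:
    """Declarative description of a simulated dataset's parameter space.

    Component flags switch whole terms of the signal model on and off; every
    enabled component's parameters carry a distribution descriptor (or a
    fixed value).  Missing descriptors for enabled components are rejected.
    """

    amplitudes: dict[str, Dist]
    lorentzian: dict[str, Dist] | Dist = field(default_factory=lambda: fixed(2.0))
    gaussian_metab: Dist = field(default_factory=lambda: fixed(0.0))
    gaussian_mm: Dist = field(default_factory=lambda: fixed(0.0))
    freq_shift: dict[str, Dist] | Dist = field(default_factory=lambda: fixed(0.0))
    global_shift_metab: Dist = field(default_factory=lambda: fixed(0.0))
    global_shift_nuisance: Dist = field(default_factory=lambda: fixed(0.0))
    phi0: Dist = field(default_factory=lambda: fixed(0.0))
    phi1: Dist = field(default_factory=lambda: fixed(0.0))
    ec_amplitude: Dist = field(default_factory=lambda: fixed(0.0))
    ec_timeconstant: Dist = field(default_factory=lambda: fixed(0.1))
    snr: Dist = field(default_factory=lambda: fixed(15.0))
    b0_mu: Dist = field(default_factory=lambda: fixed(0.0))
    b0_delta: Dist = field(default_factory=lambda: fixed(0.0))
    b0_grid_shape: tuple[int, int, int] = (10, 10, 10)
    baseline: WalkConfig = field(default_factory=baseline_profile)
    baseline_scale: Dist = field(default_factory=lambda: uniform(0.1, 0.5))
    water: WalkConfig = field(default_factory=residual_water_profile)
    water_scale: Dist = field(default_factory=lambda: uniform(0.5, 2.0))
    coil: CoilConfig = field(default_factory=CoilConfig)
    # component switches
    noise_enabled: bool = True
    noise_correlated: bool = False
    baseline_enabled: bool = False
    water_enabled: bool = False
    phases_enabled: bool = True
    eddy_enabled: bool = False
    b0_enabled: bool = False
    transients_enabled: bool = False
    # post-processing
    tl: float = 0.0
    zero_fill_len: int | None = None

    def __post_init__(self) -> None:
        if not self.amplitudes:
            raise ValueError("amplitudes must provide a descriptor per basis name")
        required = {
            "snr": (self.noise_enabled or self.transients_enabled, self.snr),
            "baseline_scale": (self.baseline_enabled, self.baseline_scale),
            "water_scale": (self.water_enabled, self.water_scale),
            "phi0": (self.phases_enabled, self.phi0),
            "phi1": (self.phases_enabled, self.phi1),
            "ec_amplitude": (self.eddy_enabled, self.ec_amplitude),
            "ec_timeconstant": (self.eddy_enabled, self.ec_timeconstant),
            "b0_mu": (self.b0_enabled, self.b0_mu),
            "b0_delta": (self.b0_enabled, self.b0_delta),
        }
        for name, (enabled, dist) in required.items():
            if enabled and dist is None:
                raise ValueError(f"component enabled but no descriptor for {name!r}")

    def _per_name(self, spec, name: str) -> Dist:
        if isinstance(spec, dict):
            if name not in spec:
                raise ValueError(f"no descriptor for parameter of metabolite {name!r}")
            return spec[name]
        return spec


# ---------------------------------------------------------------------------
# one spectrum's complete ground-truth record

@dataclass
class ParameterSample:
    """All drawn values and seeds for one spectrum; sufficient to
    re-simulate it exactly."""

    amplitudes: dict[str, float]
    lorentzian: dict[str, float]
    gaussian_metab: float
    gaussian_mm: float
    freq_shifts: dict[str, float]
    global_shift_metab: float
    global_shift_nuisance: float
    phi0: float
    phi1: float
    ec_amplitude: float
    ec_timeconstant: float
    snr0: float  # inf = noise disabled
    noise_correlated: bool
    b0: B0Params | None
    baseline: WalkConfig | None
    water: WalkConfig | None
    coil: CoilConfig | None
    noise_seed: int = 0
    baseline_seed: int = 0
    water_seed: int = 0
    coil_seed: int = 0
    tl: float = 0.0
    zero_fill_len: int | None = None

    def to_dict(self) -> dict[str, Any]:
        """JSON-safe dict (inf SNR encoded as None)."""
        d = dataclasses.asdict(self)
        d["snr0"] = None if np.isinf(self.snr0) else self.snr0
        if self.coil is not None and self.coil.noise_correlation is not None:
            d["coil"]["noise_correlation"] = np.asarray(
                self.coil.noise_correlation
            ).tolist()
        for key in ("baseline", "water"):
            if d[key] is not None:
                d[key]["ppm_span"] = list(d[key]["ppm_span"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSample":
        d = dict(d)
        d["snr0"] = np.inf if d.get("snr0") is None else float(d["snr0"])
        if d.get("b0") is not None:
            b = dict(d["b0"])
            b["grid_shape"] = tuple(b["grid_shape"])
            d["b0"] = B0Params(**b)
        for key in ("baseline", "water"):
            if d.get(key) is not None:
                w = dict(d[key])
                w["ppm_span"] = tuple(w["ppm_span"])
                d[key] = WalkConfig(**w)
        if d.get("coil") is not None:
            c = dict(d["coil"])
            c["sens_clamp"] = tuple(c["sens_clamp"])
            if c.get("noise_correlation") is not None:
                c["noise_correlation"] = np.asarray(c["noise_correlation"], dtype=float)
            d["coil"] = CoilConfig(**c)
        return cls(**d)


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def sample_parameters(
    spec: SamplingSpec, n: int, seed: int | np.random.SeedSequence
) -> list[ParameterSample]:
    """Draw ``n`` complete parameter records, deterministic under the master seed."""
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    samples = []
    for child in master.spawn(n):
        draw_ss, noise_ss, base_ss, water_ss, coil_ss = child.spawn(5)
        rng = np.random.default_rng(draw_ss)
        names = list(spec.amplitudes)
        amplitudes = {m: max(0.0, spec.amplitudes[m].sample(rng)) for m in names}
        lorentzian = {m: max(0.0, spec._per_name(spec.lorentzian, m).sample(rng)) for m in names}
        freq_shifts = {m: spec._per_name(spec.freq_shift, m).sample(rng) for m in names}
        b0 = None
        if spec.b0_enabled:
            b0 = B0Params.isotropic(
                mu=spec.b0_mu.sample(rng),
                delta=max(0.0, spec.b0_delta.sample(rng)),
                grid_shape=spec.b0_grid_shape,
            )
        samples.append(
            ParameterSample(
                amplitudes=amplitudes,
                lorentzian=lorentzian,
                gaussian_metab=max(0.0, spec.gaussian_metab.sample(rng)),
                gaussian_mm=max(0.0, spec.gaussian_mm.sample(rng)),
                freq_shifts=freq_shifts,
                global_shift_metab=spec.global_shift_metab.sample(rng),
                global_shift_nuisance=spec.global_shift_nuisance.sample(rng),
                phi0=spec.phi0.sample(rng) if spec.phases_enabled else 0.0,
                phi1=spec.phi1.sample(rng) if spec.phases_enabled else 0.0,
                ec_amplitude=spec.ec_amplitude.sample(rng) if spec.eddy_enabled else 0.0,
                ec_timeconstant=max(1e-6, spec.ec_timeconstant.sample(rng)),
                snr0=(
                    max(1e-3, spec.snr.sample(rng))
                    if (spec.noise_enabled or spec.transients_enabled)
                    else np.inf
                ),
                noise_correlated=spec.noise_correlated,
                b0=b0,
                baseline=(
                    replace(spec.baseline, scale=spec.baseline_scale.sample(rng))
                    if spec.baseline_enabled
                    else None
                ),
                water=(
                    replace(spec.water, scale=spec.water_scale.sample(rng))
                    if spec.water_enabled
                    else None
                ),
                coil=spec.coil if spec.transients_enabled else None,
                noise_seed=_spawn_seed(noise_ss),
                baseline_seed=_spawn_seed(base_ss),
                water_seed=_spawn_seed(water_ss),
                coil_seed=_spawn_seed(coil_ss),
                tl=spec.tl,
                zero_fill_len=spec.zero_fill_len,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# single-spectrum assembly

@dataclass
class SimulationResult:
    """Final FID plus the pre-artifact ground-truth components."""

    fid: np.ndarray
    metabolite_fid: np.ndarray  # noiseless metabolite-only signal ("fit")
    grid: AcquisitionGrid
    baseline: NuisanceCurve | None = None
    water: NuisanceCurve | None = None
    transients: TransientSet | None = None
    sigma: float = 0.0
    ref_height: float = 0.0


def simulate_spectrum(sample: ParameterSample, basis: BasisSet) -> SimulationResult:
    """Assemble one spectrum from a complete parameter record."""
    grid = basis.grid
    missing = [m for m in basis.names if m not in sample.amplitudes]
    if missing:
        raise KeyError(f"parameter sample missing amplitudes for {missing}")
    mparams = MetaboliteParams(
        amplitudes=sample.amplitudes,
        lorentzian=sample.lorentzian,
        gaussian_metab=sample.gaussian_metab,
        gaussian_mm=sample.gaussian_mm,
        freq_shifts=sample.freq_shifts,
        global_shift_metab=sample.global_shift_metab,
        global_shift_nuisance=sample.global_shift_nuisance,
    )
    modulator = None
    if sample.b0 is not None:
        modulator = b0_modulator(simulate_field_map(sample.b0), grid.t)
    metab_fid = scale_and_sum(basis, mparams, modulator)
    # reference height for noise scaling and nuisance magnitude matching:
    # the global max of the noiseless metabolite-only real spectrum
    ref_height = float(to_spectrum(metab_fid).real.max()) if np.any(metab_fid) else 0.0

    fid = metab_fid.copy()
    baseline = water = None
    for cfg, seed, slot in (
        (sample.baseline, sample.baseline_seed, "baseline"),
        (sample.water, sample.water_seed, "water"),
    ):
        if cfg is None:
            continue
        curve = generate_nuisance(cfg, grid.ppm, max(ref_height, 1e-30), seed)
        contrib = from_spectrum(curve.values)
        if sample.global_shift_nuisance:
            contrib = contrib * np.exp(
                -2j * np.pi * sample.global_shift_nuisance * grid.t
            )
        fid = fid + contrib
        if slot == "baseline":
            baseline = curve
        else:
            water = curve

    sigma = 0.0
    if sample.coil is None and np.isfinite(sample.snr0):
        fid, sigma = add_noise(
            fid, sample.snr0, ref_height, sample.noise_seed, sample.noise_correlated
        )

    if sample.phi0:
        fid = apply_phase0(fid, sample.phi0)
    if sample.ec_amplitude:
        fid = apply_eddy(fid, sample.ec_amplitude, sample.ec_timeconstant, grid.t)
    if sample.phi1:
        spec = to_spectrum(fid)
        spec = apply_phase1(spec, sample.phi1, grid.ppm, grid.ppm_ref)
        fid = from_spectrum(spec)

    tset = None
    if sample.coil is not None:
        tset = make_transients(
            fid, grid, sample.coil, sample.snr0, max(ref_height, 1e-30), sample.coil_seed
        )
        fid = combine_transients(tset)

    return SimulationResult(
        fid=fid,
        metabolite_fid=metab_fid,
        grid=grid,
        baseline=baseline,
        water=water,
        transients=tset,
        sigma=sigma,
        ref_height=ref_height,
    )


# ---------------------------------------------------------------------------
# post-processing

def apodize_zerofill_fft(
    fid: np.ndarray, tl: float, length: int, grid: AcquisitionGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Apodize by ``exp(-t*TL)``, zero-fill to ``length``, transform.

    Returns ``(spectrum, ppm_axis)`` on the zero-filled ascending-ppm axis.
    """
    fid = np.asarray(fid, dtype=complex)
    n = fid.shape[-1]
    if length < n:
        raise ValueError(f"zero-fill length {length} < fid length {n}")
    if tl < 0:
        raise ValueError(f"TL must be >= 0, got {tl}")
    apodized = fid * np.exp(-grid.t * tl)
    padded = np.zeros(fid.shape[:-1] + (length,), dtype=complex)
    padded[..., :n] = apodized
    spectrum = to_spectrum(padded)
    f = np.fft.fftshift(np.fft.fftfreq(length, d=grid.dwell_time))
    ppm_axis = grid.ppm_ref + (-f[::-1]) / grid.carrier_frequency
    return spectrum, ppm_axis


def crop_resample(
    spectrum: np.ndarray,
    ppm_axis: np.ndarray,
    ppm_window: tuple[float, float],
    n_out: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop to a ppm window and resample with a modified-Akima interpolant."""
    spectrum = np.asarray(spectrum)
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    lo, hi = ppm_window
    if lo >= hi:
        raise ValueError(f"ppm_window must be increasing, got {ppm_window}")
    if lo < ppm_axis.min() - 1e-12 or hi > ppm_axis.max() + 1e-12:
        raise ValueError(
            f"ppm_window {ppm_window} outside spectral axis "
            f"[{ppm_axis.min():.3f}, {ppm_axis.max():.3f}]"
        )
    new_axis = np.linspace(lo, hi, int(n_out))
    if np.iscomplexobj(spectrum):
        re = Akima1DInterpolator(ppm_axis, spectrum.real, method="makima")(new_axis)
        im = Akima1DInterpolator(ppm_axis, spectrum.imag, method="makima")(new_axis)
        return re + 1j * im, new_axis
    return Akima1DInterpolator(ppm_axis, spectrum, method="makima")(new_axis), new_axis


# ---------------------------------------------------------------------------
# batches

@dataclass
class SpectralDataset:
    """A batch of simulated FIDs/spectra with paired ground truths."""

    grid: AcquisitionGrid
    fids: np.ndarray  # (n, n_points) complex
    samples: list[ParameterSample]
    metabolite_fids: np.ndarray
    baselines: np.ndarray  # (n, n_points) complex, zero rows when disabled
    waters: np.ndarray
    spectra: np.ndarray | None = None
    spectra_ppm: np.ndarray | None = None
    transients: np.ndarray | None = None  # (n, C, n_points)
    sigmas: np.ndarray | None = None

    def __len__(self) -> int:
        return self.fids.shape[0]


def simulate_dataset(
    spec: SamplingSpec,
    basis: BasisSet,
    n: int,
    seed: int,
    produce_spectra: bool = True,
    chunk_size: int = 256,
) -> SpectralDataset:
    """Simulate ``n`` spectra under a sampling spec with a master seed.

    Spectra are processed in chunks of ``chunk_size`` to bound memory; the
    result is identical to simulating each spectrum individually with its
    per-spectrum record.
    """
    samples = sample_parameters(spec, n, seed)
    grid = basis.grid
    npts = grid.n_points
    fids = np.empty((n, npts), dtype=complex)
    metab = np.empty((n, npts), dtype=complex)
    baselines = np.zeros((n, npts), dtype=complex)
    waters = np.zeros((n, npts), dtype=complex)
    sigmas = np.zeros(n)
    tr = None
    if spec.transients_enabled:
        tr = np.empty((n, spec.coil.n_transients, npts), dtype=complex)
    for start in range(0, n, max(1, int(chunk_size))):
        for i in range(start, min(n, start + max(1, int(chunk_size)))):
            res = simulate_spectrum(samples[i], basis)
            fids[i] = res.fid
            metab[i] = res.metabolite_fid
            if res.baseline is not None:
                baselines[i] = res.baseline.values
            if res.water is not None:
                waters[i] = res.water.values
            sigmas[i] = res.sigma
            if tr is not None and res.transients is not None:
                tr[i] = res.transients.fids
    spectra = spectra_ppm = None
    if produce_spectra:
        length = spec.zero_fill_len or npts
        spectra, spectra_ppm = apodize_zerofill_fft(fids, spec.tl, length, grid)
    return SpectralDataset(
        grid=grid,
        fids=fids,
        samples=samples,
        metabolite_fids=metab,
        baselines=baselines,
        waters=waters,
        spectra=spectra,
        spectra_ppm=spectra_ppm,
        transients=tr,
        sigmas=sigmas,
    )
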