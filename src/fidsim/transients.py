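"""Multi-coil / multi-average transient synthesis and recombination.

A *transient* is one pre-combination signal: a single coil element's
measurement or one signal average.  The coil operator turns a clean
(noiseless) combined FID into C transients

    transient_c = sens_c * fid * exp(-1j*2*pi*df_c*t) * exp(-1j*dphi_c*pi/180)
                  + noise_c

with clamped-Gaussian coil sensitivities ``sens_c``, per-transient frequency
and zero-order phase drifts, and noise scaled so each transient hits its own
SNR target.  Per-transient SNR targets average ``snr0 / sqrt(C)`` so that
averaging the C transients recovers the combined target ``snr0`` — the
square-root-of-transients SNR gain of signal averaging.

Multi-coil and multi-average acquisitions share this one code path; they
differ only in which artifact ranges are configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artifacts import add_noise, apply_phase0
from .grid import AcquisitionGrid
from .lineshape import apply_freq_shift

__all__ = [
    "CoilConfig",
    "TransientRecord",
    "TransientSet",
    "sample_sensitivities",
    "sample_transient_snrs",
    "make_transients",
    "rebuild_transient",
    "combine_transients",
]


@dataclass(frozen=True)
class CoilConfig:
    """Configuration of the coil operator."""

    n_transients: int = 8
    sens_mu: float = 1.0
    sens_std: float = 0.5
    sens_clamp: tuple[float, float] = (0.0, 2.0)
    snr_spread: float = 0.05  # relative SD of per-transient SNR factors
    drift_freq_range: float = 5.0  # Hz, drifts drawn uniform in +-range
    drift_phase_range: float = 20.0  # degrees
    noise_correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_transients < 1:
            raise ValueError(f"n_transients must be >= 1, got {self.n_transients}")
        if not self.sens_clamp[0] < self.sens_clamp[1]:
            raise ValueError(f"sens_clamp must be ordered, got {self.sens_clamp}")
        if self.snr_spread < 0:
            raise ValueError("snr_spread must be >= 0")
        if self.noise_correlation is not None:
            r = np.asarray(self.noise_correlation, dtype=float)
            c = self.n_transients
            if r.shape != (c, c):
                raise ValueError(f"noise_correlation must be {c}x{c}, got {r.shape}")
            if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
                raise ValueError("noise_correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise ValueError("noise_correlation must be positive semidefinite")


@dataclass
class TransientRecord:
    """Ground truth for one transient: re-applying it to the clean FID
    with its noise seed reproduces the transient exactly."""

    sensitivity: float
    snr_target: float
    freq_drift_hz: float
    phase_drift_deg: float
    noise_seed: int | None


@dataclass
class TransientSet:
    """C transients on one grid plus their per-transient ground truths."""

    fids: np.ndarray  # (C, n_points) complex
    records: list[TransientRecord]
    grid: AcquisitionGrid
    correlated_seed: int | None = None
    sigma: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_transients(self) -> int:
        return self.fids.shape[0]


def sample_sensitivities(cfg: CoilConfig, rng: np.random.Generator | int) -> np.ndarray:
    """Clamped-Gaussian coil sensitivities (defaults N(1.0, 0.5) clamped to [0, 2])."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    draws = rng.normal(cfg.sens_mu, cfg.sens_std, size=cfg.n_transients)
    return np.clip(draws, *cfg.sens_clamp)


def sample_transient_snrs(
    snr0: float, cfg: CoilConfig, rng: np.random.Generator | int
) -> np.ndarray:
    """Per-transient SNR targets: mean ``snr0 / sqrt(C)`` with narrow-normal spread."""
    if not snr0 > 0:
        raise ValueError(f"snr0 must be positive, got {snr0}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    base = snr0 / np.sqrt(cfg.n_transients)
    factors = rng.normal(1.0, cfg.snr_spread, size=cfg.n_transients)
    return base * np.clip(factors, 1e-3, None)


def _transient_signal(
    clean_fid: np.ndarray, rec: TransientRecord, t: np.ndarray
) -> np.ndarray:
    sig = rec.sensitivity * np.asarray(clean_fid, dtype=complex)
    sig = apply_freq_shift(sig, rec.freq_drift_hz, t)
    return apply_phase0(sig, rec.phase_drift_deg)


def make_transients(
    clean_fid: np.ndarray,
    grid: AcquisitionGrid,
    cfg: CoilConfig,
    snr0: float,
    ref_height: float,
    seed: int | np.random.SeedSequence,
) -> TransientSet:
    """Synthesize C transients from a clean (noiseless) combined FID.

    Noise deferred from the single-spectrum stage is applied here, one
    scaled vector per transient (optionally correlated across transients via
    ``cfg.noise_correlation``).  Every transient's ground-truth record plus
    its noise seed suffice to rebuild it bit-exactly.
    """
    clean_fid = np.asarray(clean_fid, dtype=complex)
    if clean_fid.shape != (grid.n_points,):
        raise ValueError(
            f"clean_fid shape {clean_fid.shape} does not match grid ({grid.n_points},)"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    c = cfg.n_transients
    param_seed, *noise_seeds = ss.spawn(c + 1)
    rng = np.random.default_rng(param_seed)
    sens = sample_sensitivities(cfg, rng)
    snrs = sample_transient_snrs(snr0, cfg, rng)
    dfs = rng.uniform(-cfg.drift_freq_range, cfg.drift_freq_range, size=c)
    dphis = rng.uniform(-cfg.drift_phase_range, cfg.drift_phase_range, size=c)

    records = []
    fids = np.empty((c, grid.n_points), dtype=complex)
    sigmas = np.empty(c)
    seed_ints = [int(s.generate_state(1)[0] % (2**31)) for s in noise_seeds]
    if cfg.noise_correlation is None:
        for i in range(c):
            rec = TransientRecord(
                sensitivity=float(sens[i]),
                snr_target=float(snrs[i]),
                freq_drift_hz=float(dfs[i]),
                phase_drift_deg=float(dphis[i]),
                noise_seed=seed_ints[i],
            )
            sig = _transient_signal(clean_fid, rec, grid.t)
            # each transient's noise references its own (sensitivity-scaled)
            # signal height so it meets its individual SNR target
            fids[i], sigmas[i] = add_noise(
                sig, snrs[i], sens[i] * ref_height, seed_ints[i]
            )
            records.append(rec)
        return TransientSet(fids=fids, records=records, grid=grid, sigma=sigmas)

    # correlated noise: one joint draw across the transient dimension
    joint_seed = seed_ints[0]
    rng_n = np.random.default_rng(joint_seed)
    n = grid.n_points
    sig_scale = np.array([sens[i] * ref_height / snrs[i] for i in range(c)]) / np.sqrt(n)
    chol = np.linalg.cholesky(
        np.asarray(cfg.noise_correlation, dtype=float) + 1e-12 * np.eye(c)
    )
    noise = (chol @ rng_n.normal(size=(c, n))) * sig_scale[:, None] + 1j * (
        chol @ rng_n.normal(size=(c, n))
    ) * sig_scale[:, None]
    for i in range(c):
        rec = TransientRecord(
            sensitivity=float(sens[i]),
            snr_target=float(snrs[i]),
            freq_drift_hz=float(dfs[i]),
            phase_drift_deg=float(dphis[i]),
            noise_seed=None,
        )
        fids[i] = _transient_signal(clean_fid, rec, grid.t) + noise[i]
        sigmas[i] = sig_scale[i] * np.sqrt(n)
        records.append(rec)
    return TransientSet(
        fids=fids, records=records, grid=grid, correlated_seed=joint_seed, sigma=sigmas
    )


def rebuild_transient(tset: TransientSet, index: int, clean_fid: np.ndarray) -> np.ndarray:
    """Re-simulate one (uncorrelated-noise) transient from its ground truth."""
    rec = tset.records[index]
    if rec.noise_seed is None:
        raise ValueError("per-transient rebuild requires uncorrelated noise mode")
    sig = _transient_signal(np.asarray(clean_fid, dtype=complex), rec, tset.grid.t)
    # stored sigma = sens*ref_height/snr_target, so sens*ref_height = sigma*snr
    noisy, _ = add_noise(
        sig, rec.snr_target, rec.snr_target * tset.sigma[index], rec.noise_seed
    )
    return noisy


def combine_transients(
    tset: TransientSet,
    weights: np.ndarray | None = None,
    mode: str = "average",
) -> np.ndarray:
    """Weighted recombination of transients into one FID.

    Both modes normalize by the weight sum (summation without normalization
    would inflate the amplitude with C); ``sum`` exists for protocol
    fidelity and gives the identical result by construction.
    """
    if mode not in ("average", "sum"):
        raise ValueError(f"mode must be 'average' or 'sum', got {mode!r}")
    c = tset.n_transients
    w = np.ones(c) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (c,):
        raise ValueError(f"weights must have length {c}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return (w[:, None] * tset.fids).sum(axis=0) / total
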