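# Methods

This note documents the signal model implemented by `fidsim`, the
conventions that tie its operators together, the choices made where the
design was genuinely open, and what the synthetic test conditions do and do
not establish about real data.

## Model overview and assembly order

A simulated spectrum is a linear combination of metabolite basis functions
subjected, in order, to: amplitude scaling → Voigt lineshape → sub-voxel B0
modulation → per-metabolite frequency shift → summation (plus a
metabolite-group global shift) → addition of baseline and residual-water
nuisance signals → noise at a requested spectral SNR → zero-order phase and
eddy currents (time domain) and first-order phase (frequency domain) →
optionally the coil operator (C transients; noise is deferred to this stage
when it is enabled) → optional apodization, zero-filling, FFT and
crop/resampling. The order mirrors the physical acquisition chain: lineshape
and field effects act on each metabolite's signal, nuisance signals and
noise add to the combined signal, and receive-chain phase errors multiply
everything, noise included (they are unitary, so the measured SNR is
unaffected by their placement).

Assumptions inherited from the model class: basis functions fully describe
each metabolite's response for the pulse sequence at hand (the simulator
never re-simulates spin physics); one Lorentzian rate per metabolite and one
Gaussian rate per group (metabolites vs. macromolecules/lipids), not
per-moiety; nuisance signals have no physical model and are represented
semi-parametrically; noise is complex Gaussian (no Rician or quantization
effects); all artifacts are mutually independent draws.

## Conventions that everything else references

* **Time axis** starts exactly at t = 0 (first FID sample at the echo);
  acquisition delay is modeled through the first-order phase, not a hidden
  dead time.
* **One FFT convention** (`fidsim.fourier`): unnormalized FFT, center-
  shifted, reordered so the ppm axis is ascending and multiplication of the
  FID by `e^{−i2πft}` displaces the spectrum toward **higher** ppm by
  `f/carrier` ppm. Every frequency-signed operation (frequency shifts, B0
  offsets, eddy long-time-constant limit, toy-basis line placement) is
  defined against this convention and pinned by peak-picking tests so it
  cannot drift. Under this transform a time-domain complex noise vector
  with per-channel SD `s` yields spectral channels with SD `s·√n`; this
  factor is unit-tested and used to convert the frequency-domain noise SD
  `σ = ref_height/snr₀` into the time-domain draw.
* **ppm axis** stored ascending internally; conventional display
  orientation (high ppm left) is a plotting concern.
* **Defaults**: carrier 127.7 MHz (3 T ¹H), reference 4.65 ppm (water),
  2048 points at 2000 Hz spectral width — the standing acquisition
  condition used throughout the tests and examples.

## Parameters that matter

| parameter | units | default | meaning |
|---|---|---|---|
| `M_n` | mM | — | amplitude per basis function (1 basis unit = 1.0 mM) |
| `d_n` | 1/s | 2 | Lorentzian rate; spectral FWHM `d/π` Hz |
| `g` | 1/s² | 0 | Gaussian rate, one per group |
| `Δf_n`, global shifts | Hz | 0 | per-metabolite and group-level frequency offsets |
| `μ, Δ=2dx=2dy=2dz` | Hz | 0 | B0 field-map mean and isotropic spread |
| `snr₀` | linear | 15 | spectral SNR target (max real peak / noise SD) |
| `φ₀` | deg | 0 | zero-order phase |
| `φ₁` | deg/ppm | 0 | first-order phase, pivot at 4.65 ppm |
| `A₀, tc₀` | Hz, s | 0, 0.1 | eddy-current amplitude and time constant |
| `C, sens ~ N(1, 0.5) clamp [0,2]` | — | 8 | transient count and sensitivity sampler |
| `snr_spread` | rel. | 0.05 | per-transient SNR factor SD ("narrow normal") |
| drift ranges | Hz, deg | ±5, ±20 | per-transient frequency/phase drifts |
| `TL` | 1/s | 0 | apodization rate; apodized Lorentzian FWHM `(d+TL)/π` |

## B0 field maps

The voxel is discretized into `round(spectro_voxel/anat_voxel)` points per
axis (≥1). A linear gradient assigns `offset = μ + dx·u + dy·v + dz·w` with
`u, v, w` symmetric midpoint coordinates `(2k+1−G)/G`: grid points represent
anatomical-voxel centers, the map mean is exactly μ for every grid shape,
and the modulator converges to the continuum limit (for a 1-D gradient,
sinc damping `sin(2π·dx·t)/(2π·dx·t)`, verified within 1% at G = 101). The
sampled extreme corners are `μ ± d(G−1)/G`, approaching `μ ± dx ± dy ± dz`
as the grid refines. The voxel-average phase factor is normalized by R so
that `|m(0)| = 1`; an unnormalized sum would scale signal amplitude with
sub-voxel resolution, which is an artifact of discretization, not physics.
Non-linear gradient profiles plug in as per-axis coordinate transforms.
For the (common, separable) linear map the modulator is computed exactly as
the product of per-axis 1-D averages; non-separable plug-in maps fall back
to the direct voxel sum.

## Nuisance generator

Both the baseline and the residual water region come from one bounded
smoothed walk: cumulative-sum Gaussian steps; a linear trend between the
requested endpoint values; deltas defined as the walk's deviations from its
own endpoint line (so the trend carries the endpoints and the deltas carry
only noise — with zero step SD the output is exactly the trend); deltas
renormalized to the bound width; the composed curve clipped pointwise into
`[lower_bound, upper_bound]`; uniform smoothing with kernel
`max(1, round(window_size·length))` and reflective padding. Clipping the
composed curve (rather than the deltas alone) is what guarantees the bound
invariant for every configuration, and smoothing is a convex combination so
bounds survive it. Profiles: baseline `window_size = 0.15`, span
0.2–4.2 ppm, scale ~0.1–0.5 of the spectrum maximum; residual water
`window_size = 0.02`, span 4.2–5.1 ppm, scale ~0.5–2. These profile values
are configuration defaults chosen to reproduce the qualitative contrast
between broad smooth baselines and irregular water regions, not claims
about in vivo truth; scenario-appropriate ranges are the user's call.

Curves are generated on the spectral axis, resampled onto the acquisition
ppm axis (cubic interpolation, zero outside the span), completed with their
90° quadrature partner via the analytic signal (for a Lorentzian absorption
input this reproduces the closed-form dispersion curve within 2% away from
span edges), and carried into the time-domain sum through the inverse of
the package FFT. Exported nuisance curves are the pre-artifact ground
truths: later phase/eddy/coil artifacts are applied to the combined signal
but never to the stored components.

## Noise and SNR

Spectral SNR is the maximum real-channel peak height divided by one noise
SD. The reference height defaults to the global maximum of the noiseless
metabolite-only real spectrum (a named-metabolite reference is available),
which makes the requested and measured SNR agree by construction: over 100
seeded realizations the mean measured SNR at a request of 15 is within 3%.
The default measurement region is the highest-ppm 10% of the axis
(signal-free for the built-in toy basis), overridable. Real and imaginary
noise channels are independent by default; a correlated mode draws one
vector and synthesizes the imaginary channel as its quadrature partner.

## Transients

Per-transient SNR targets average `snr₀/√C` — the only scaling under which
the √C averaging gain recovers the combined target. Each transient's noise
references its own sensitivity-scaled signal height, so each meets its
individual target; inter-coil noise correlation is available through a
user-supplied correlation matrix (Cholesky mixing, verified within 0.05 at
n = 4096). Drifts are independent uniform draws per transient; a
scanner-heating-style trend across transients is not modeled. Combination
always normalizes by the weight sum; `sum` mode exists for protocol
fidelity and equals `average` by construction. Multi-coil and multi-average
simulation are one code path with different configuration emphases.

## Numerical choices

* Eddy phase read as `φ(t) = 2π·A₀·t·e^{−t/tc₀}`: the only grouping that
  reproduces both documented limits (tc₀ much longer than the acquisition →
  a pure +A₀ Hz shift; short tc₀ → a transient lineshape distortion).
* Phase0/phase1 preserve the spectral magnitude pointwise. The eddy
  operator necessarily does not (reshaping the spectrum *is* the artifact);
  its unitarity is expressed as pointwise time-domain modulus preservation
  plus total spectral energy (Parseval) preservation, and tested as such.
* Crop/resample uses the modified-Akima interpolant (scipy `makima`),
  exact at coincident nodes and on affine data.
* Toy basis functions are normalized to unit noiseless spectral maximum,
  making "1 basis unit = 1.0 mM" numerically concrete.
* Degenerate inputs: zero amplitudes → zero signal; `snr₀ = inf` is the
  documented no-noise sentinel; zero-spread walks short-circuit to the
  trend; all-zero nuisance curves cannot be scaled to a nonzero magnitude
  and are rejected; grid/length mismatches are rejected naming the
  offender.
* Seeding: a master `SeedSequence` spawns independent child seeds per
  spectrum and per component (noise, baseline, water, coil), all stored in
  the parameter record; batch simulation equals per-record simulation, and
  a record plus the basis reproduces its spectrum bit-exactly, through
  JSON and HDF5 round trips included.

## Synthetic test conditions — what they show and what they do not

The standing fixture is a three-singlet "brain-like" basis (NAA 2.01, Cr
3.03, Cho 3.22 ppm; T2* 0.1 s; amplitudes 1.0/0.8/0.6 when fixed) on the
default grid — chosen so peaks are well separated, the default noise
region is signal-free, and every closed-form oracle (peak position, FWHM,
displacement) is unambiguous. Problem sizes used by the test suite and the
acceptance script — 100 noise realizations, 10⁶ sensitivity draws, 50
replicates × C ∈ {2,4,8} for the averaging gain, 1000 random walk
configurations — were chosen as the smallest sizes at which Monte-Carlo
error is comfortably below the asserted tolerances; everything runs in
seconds on one CPU.

Passing these tests establishes that the operators implement their
definitions and limits correctly and that the pipeline is deterministic
and ground-truth-complete. It does **not** establish in vivo realism:
singlet toy bases have no J-coupled multiplet structure, real basis sets
(from density-matrix simulators) must be supplied for realistic spectra,
nuisance profiles are qualitative stand-ins for phenomena without a
physical model, and all parameter ranges shipped as defaults are starting
points — matching a specific scanner, sequence and population remains the
user's responsibility.

## Known limitations

No quantum-mechanical basis simulation (basis sets are consumed, not
produced); no moiety-level T2 or frequency tables; no Rician/colored noise;
no MRSI spatial grids, J-difference editing, diffusion or 2D acquisitions;
no alignment/correction algorithms (the simulator produces the artifacts
those methods remove, with the ground truths needed to score them); no
vendor raw-format readers — I/O is the package's HDF5 container plus
NIfTI-MRS.
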