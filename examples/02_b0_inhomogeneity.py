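"""B0 inhomogeneity: line broadening, signal damping and frequency shift.

A linear-gradient field map over the voxel is summarized by its mean offset
mu (Hz) and isotropic spread Delta = 2dx = 2dy = 2dz (Hz).  The voxel-average
phase modulator damps and shifts the metabolite signal: mu moves the peaks,
Delta broadens them and lowers their intensity.
"""

import fidsim as fs
from fidsim.fourier import to_spectrum

grid = fs.build_grid(2048, 2000.0, 127.7, 4.65)
naa = fs.toy_brain_basis(grid)["NAA"].fid
base_ppm = fs.peak_ppm(naa, grid)
base_height = to_spectrum(naa).real.max()

print(f"no B0 distortion: NAA peak at {base_ppm:.3f} ppm, height {base_height:.3f}")
for mu, delta in [(10.0, 0.0), (0.0, 5.0), (10.0, 5.0)]:
    p = fs.B0Params.isotropic(mu=mu, delta=delta, grid_shape=(10, 10, 10))
    mod = fs.b0_modulator(fs.simulate_field_map(p), grid.t)
    distorted = fs.apply_b0(naa, mod)
    shift_hz = (fs.peak_ppm(distorted, grid) - base_ppm) * grid.carrier_frequency
    height = to_spectrum(distorted).real.max()
    print(f"mu={mu:5.1f} Hz, Delta={delta:4.1f} Hz -> "
          f"peak shift {shift_hz:+6.2f} Hz, height {height:.3f}")
print("-> the mean offset sets the shift; the spread damps the signal.")
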