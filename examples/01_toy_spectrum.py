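"""Simulate a clean and a noisy toy brain spectrum and measure its SNR.

Builds the built-in three-singlet basis (NAA 2.01, Cr 3.03, Cho 3.22 ppm),
scales it with millimolar concentrations, applies a Voigt lineshape, adds
noise at a requested spectral SNR of 15 and measures the SNR back from the
spectrum (max real peak height / noise-region SD).
"""

import numpy as np

import fidsim as fs
from fidsim.fourier import to_spectrum

basis = fs.toy_brain_basis()  # 2048 points, 2000 Hz, 3 T 1H grid
params = fs.MetaboliteParams(
    amplitudes={"NAA": 12.0, "Cr": 8.0, "Cho": 2.0},  # mM
    lorentzian={n: 4.0 for n in basis.names},  # 1/s
    gaussian_metab=20.0,  # 1/s^2
)
clean = fs.scale_and_sum(basis, params)
ref_height = to_spectrum(clean).real.max()

noisy, sigma = fs.add_noise(clean, 15.0, ref_height, 0)
snr = fs.measure_snr(to_spectrum(noisy))

print(f"peak positions (ppm): "
      f"{[round(fs.peak_ppm(basis[n].fid, basis.grid), 2) for n in basis.names]}")
print(f"noise sigma = {sigma:.4f} (spectral units), requested SNR = 15")
print(f"measured SNR = {snr:.2f}")
print("-> the measured SNR fluctuates around the requested value; averaging"
      " it over many seeds converges to 15.")
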