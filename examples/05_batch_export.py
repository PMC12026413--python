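"""Batch simulation with randomly sampled parameters, export, re-simulation.

Defines a sampling spec (distribution per parameter, component switches),
simulates a seeded batch, exports it to the HDF5 container and NIfTI-MRS,
then proves the ground-truth guarantee: every exported parameter record
re-simulates its spectrum bit-exactly.
"""

import tempfile
from pathlib import Path

import numpy as np

import fidsim as fs

basis = fs.toy_brain_basis()
spec = fs.SamplingSpec(
    amplitudes={"NAA": fs.uniform(7.5, 17.0), "Cr": fs.uniform(4.0, 11.5),
                "Cho": fs.uniform(0.5, 2.5)},
    lorentzian=fs.uniform(2.0, 8.0),
    gaussian_metab=fs.uniform(0.0, 200.0),
    snr=fs.fixed(15.0),
    phi0=fs.uniform(-20.0, 20.0),
    phi1=fs.uniform(-5.0, 5.0),
    baseline_enabled=True,
    water_enabled=True,
    b0_enabled=True,
    b0_mu=fs.uniform(-10.0, 10.0),
    b0_delta=fs.uniform(0.0, 4.0),
)
ds = fs.simulate_dataset(spec, basis, n=8, seed=2026)
print(f"simulated {len(ds)} spectra, {ds.fids.shape[1]} points each")
s0 = ds.samples[0]
print(f"spectrum 0 ground truth: NAA={s0.amplitudes['NAA']:.2f} mM, "
      f"d_NAA={s0.lorentzian['NAA']:.2f} 1/s, phi0={s0.phi0:+.1f} deg, "
      f"B0 mu={s0.b0.mu:+.2f} Hz")

with tempfile.TemporaryDirectory() as tmp:
    h5 = Path(tmp) / "run.h5"
    nii = Path(tmp) / "run.nii.gz"
    fs.write_dataset(ds, h5, manifest={"seed": 2026})
    fs.write_nifti_mrs(ds, nii)
    back = fs.read_dataset(h5)
    res = fs.simulate_spectrum(back.samples[0], basis)
    exact = np.array_equal(res.fid, ds.fids[0])
    data, hdr, dwell = fs.read_nifti_mrs(nii)
    print(f"container round trip exact: {np.array_equal(back.fids, ds.fids)}")
    print(f"re-simulation from exported record bit-exact: {exact}")
    print(f"NIfTI-MRS: shape {data.shape}, dwell {dwell} s, "
          f"f0 {hdr['SpectrometerFrequency'][0]} MHz, {hdr['ResonantNucleus'][0]}")
print("-> every spectrum is exactly reproducible from its exported record;"
      " that is the point of simulating with known ground truths.")
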