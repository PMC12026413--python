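"""Dataset export: HDF5 container and NIfTI-MRS.

The container holds the complex data, every ground-truth component and the
full parameter records (as JSON), so any exported spectrum can be
re-simulated exactly.  NIfTI-MRS export writes complex time-domain data in
the standard single-voxel layout (1 x 1 x 1 x time [x transients x batch])
with dwell time in pixdim[4] and the spectroscopy header fields
(SpectrometerFrequency, ResonantNucleus, dimension tags) in a JSON header
extension.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .grid import build_grid
from .pipeline import ParameterSample, SpectralDataset

__all__ = ["write_dataset", "read_dataset", "write_nifti_mrs", "read_nifti_mrs"]

NIFTI_MRS_ECODE = 44  # registered NIfTI-MRS JSON header-extension code


def write_dataset(dataset: SpectralDataset, path, manifest: dict | None = None) -> None:
    """Write a simulated dataset (data + ground truths + parameters) to HDF5."""
    with h5py.File(path, "w") as f:
        g = dataset.grid
        f.attrs["n_points"] = g.n_points
        f.attrs["spectral_width_hz"] = g.spectral_width
        f.attrs["carrier_frequency_mhz"] = g.carrier_frequency
        f.attrs["ppm_ref"] = g.ppm_ref
        if manifest:
            f.attrs["manifest"] = json.dumps(manifest)
        f.create_dataset("fids", data=dataset.fids)
        gt = f.create_group("ground_truth")
        gt.create_dataset("metabolite_fids", data=dataset.metabolite_fids)
        gt.create_dataset("baselines", data=dataset.baselines)
        gt.create_dataset("residual_water", data=dataset.waters)
        if dataset.sigmas is not None:
            gt.create_dataset("noise_sigma", data=dataset.sigmas)
        if dataset.spectra is not None:
            f.create_dataset("spectra", data=dataset.spectra)
            f.create_dataset("spectra_ppm", data=dataset.spectra_ppm)
        if dataset.transients is not None:
            f.create_dataset("transients", data=dataset.transients)
        params = [json.dumps(s.to_dict()) for s in dataset.samples]
        f.create_dataset("parameters", data=params, dtype=h5py.string_dtype())


def read_dataset(path) -> SpectralDataset:
    """Read a dataset container written by :func:`write_dataset`."""
    with h5py.File(path, "r") as f:
        grid = build_grid(
            int(f.attrs["n_points"]),
            float(f.attrs["spectral_width_hz"]),
            float(f.attrs["carrier_frequency_mhz"]),
            float(f.attrs["ppm_ref"]),
        )
        samples = [
            ParameterSample.from_dict(json.loads(p)) for p in f["parameters"].asstr()[()]
        ]
        return SpectralDataset(
            grid=grid,
            fids=f["fids"][()],
            samples=samples,
            metabolite_fids=f["ground_truth/metabolite_fids"][()],
            baselines=f["ground_truth/baselines"][()],
            waters=f["ground_truth/residual_water"][()],
            sigmas=(
                f["ground_truth/noise_sigma"][()]
                if "ground_truth/noise_sigma" in f
                else None
            ),
            spectra=f["spectra"][()] if "spectra" in f else None,
            spectra_ppm=f["spectra_ppm"][()] if "spectra_ppm" in f else None,
            transients=f["transients"][()] if "transients" in f else None,
        )


def write_nifti_mrs(dataset: SpectralDataset, path, nucleus: str = "1H") -> None:
    """Write the batch's complex FIDs (and transients, if any) as NIfTI-MRS."""
    g = dataset.grid
    if dataset.transients is not None:
        # (x, y, z, time, coil, batch)
        data = np.transpose(dataset.transients, (2, 1, 0))[None, None, None, ...]
        dim_tags = {"dim_5": "DIM_COIL", "dim_6": "DIM_USER_0"}
    else:
        data = np.transpose(dataset.fids, (1, 0))[None, None, None, ...]
        dim_tags = {"dim_5": "DIM_USER_0"}
    header = {
        "SpectrometerFrequency": [g.carrier_frequency],
        "ResonantNucleus": [nucleus],
        **dim_tags,
    }
    img = nib.Nifti2Image(data.astype(np.complex64), affine=np.eye(4))
    img.header["pixdim"][4] = g.dwell_time
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension(NIFTI_MRS_ECODE, json.dumps(header).encode("utf-8"))
    )
    nib.save(img, path)


def read_nifti_mrs(path) -> tuple[np.ndarray, dict, float]:
    """Read a NIfTI-MRS file: (data, spectroscopy header dict, dwell time s)."""
    img = nib.load(path)
    hdr = None
    for ext in img.header.extensions:
        if ext.get_code() == NIFTI_MRS_ECODE:
            content = ext.get_content()
            if isinstance(content, bytes):
                content = content.decode("utf-8")
            hdr = json.loads(content)
    if hdr is None:
        raise ValueError(f"{path} carries no NIfTI-MRS header extension")
    data = np.asanyarray(img.dataobj)
    dwell = float(img.header["pixdim"][4])
    return data, hdr, dwell
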