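"""HDF5 / NIfTI / CSV persistence for datasets, volumes and traces."""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import KSpaceDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_volume",
    "load_volume",
    "save_motion_trace",
    "load_motion_trace",
]


def save_dataset(path, data: KSpaceDataset) -> None:
    """Write a k-space dataset to the HDF5 container.

    Layout: datasets ``/kspace`` (complex), ``/line_coords`` (int),
    ``/parity`` (int), ``/inav`` (complex); every meta entry becomes a root
    attribute (non-scalar entries are JSON-encoded).
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=data.lines)
        f.create_dataset("line_coords", data=data.line_coords)
        f.create_dataset("parity", data=data.parity)
        f.create_dataset("inav", data=data.inavs)
        for k, v in data.meta.items():
            if isinstance(v, (list, dict, tuple)):
                f.attrs[k] = json.dumps(v)
                f.attrs[f"__json__{k}"] = True
            else:
                f.attrs[k] = v


def load_dataset(path) -> KSpaceDataset:
    with h5py.File(path, "r") as f:
        meta = {}
        for k, v in f.attrs.items():
            if k.startswith("__json__"):
                continue
            if f.attrs.get(f"__json__{k}", False):
                v = json.loads(v)
            elif isinstance(v, bytes):
                v = v.decode()
            elif isinstance(v, np.generic):
                v = v.item()
            meta[k] = v
        return KSpaceDataset(
            lines=f["kspace"][...],
            line_coords=f["line_coords"][...],
            parity=f["parity"][...],
            inavs=f["inav"][...],
            meta=meta,
        )


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def save_volume(path, volume) -> None:
    """Write an ImageVolume as NIfTI (RAS affine from the voxel spacing).

    Complex volumes are stored as a trailing length-2 (re, im) axis so both
    channels survive losslessly; the contrast tag goes in the description.
    """
    vox = volume.voxels
    if np.iscomplexobj(vox):
        arr = np.stack([vox.real, vox.imag], axis=-1).astype(np.float64)
    else:
        arr = np.asarray(vox, np.float64)
    img = nib.Nifti1Image(arr, _affine(volume.spacing_mm))
    img.header["descrip"] = volume.tag.encode()[:79]
    nib.save(img, str(path))


def load_volume(path):
    from .recon import ImageVolume

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    tag = img.header["descrip"].tobytes().split(b"\x00")[0].decode()
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    if arr.ndim == 4 and arr.shape[-1] == 2:
        arr = arr[..., 0] + 1j * arr[..., 1]
    return ImageVolume(voxels=arr, spacing_mm=spacing, tag=tag or "magnitude")


def save_motion_trace(path, trace) -> None:
    pd.DataFrame({
        "beat": np.arange(len(trace.dy_mm)),
        "parity": trace.parity,
        "dx_mm": trace.dx_mm,
        "dy_mm": trace.dy_mm,
        "score": trace.score,
    }).to_csv(path, index=False)


def load_motion_trace(path):
    from .motion import MotionTrace

    df = pd.read_csv(path)
    return MotionTrace(
        dy_mm=df["dy_mm"].to_numpy(),
        dx_mm=df["dx_mm"].to_numpy(),
        parity=df["parity"].to_numpy(),
        score=df["score"].to_numpy(),
    )
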