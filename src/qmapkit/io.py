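"""NIfTI-1 helpers: volumes carry mm voxel sizes in the affine."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(data: np.ndarray, voxel_size, path, dtype=np.float32,
               descrip: str | None = None) -> None:
    """Write a volume (3D or 4D) with a diagonal mm affine."""
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a volume; returns (data, voxel_size_mm)."""
    img = nib.load(str(Path(path)))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)
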