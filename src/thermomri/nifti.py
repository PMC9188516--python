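"""Thin NIfTI I/O helpers over nibabel."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume"]


def save_volume(data: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write an array as NIfTI-1 with a diagonal affine from voxel size (mm)."""
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_size[:3]) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_volume(path) -> tuple:
    """Read a NIfTI volume -> (data array, voxel size in mm)."""
    img = nib.load(str(Path(path)))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.get_fdata()), tuple(float(z) for z in zooms)
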