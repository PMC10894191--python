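"""Minimal NIfTI round-tripping for voxel maps and 4-D datasets."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_map", "load_map", "save_timeseries", "load_timeseries"]


def save_map(
    values: np.ndarray,
    grid_shape: tuple[int, int, int],
    path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Write a flat per-voxel map as a 3-D NIfTI image."""
    vol = np.asarray(values, float).reshape(grid_shape)
    nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)), str(path))


def load_map(path: str | Path) -> np.ndarray:
    """Read a 3-D NIfTI image back to a flat per-voxel array."""
    return np.asarray(nib.load(str(path)).get_fdata()).reshape(-1)


def save_timeseries(
    data: np.ndarray,
    grid_shape: tuple[int, int, int],
    path: str | Path,
    tr: float = 2.0,
) -> None:
    """Write a volumes x voxels matrix as a 4-D NIfTI (x, y, z, t)."""
    vol = np.asarray(data, float).T.reshape(*grid_shape, data.shape[0])
    img = nib.Nifti1Image(vol, np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    nib.save(img, str(path))


def load_timeseries(path: str | Path) -> np.ndarray:
    """Read a 4-D NIfTI back to a volumes x voxels matrix."""
    vol = np.asarray(nib.load(str(path)).get_fdata())
    return vol.reshape(-1, vol.shape[-1]).T
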