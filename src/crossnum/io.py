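"""NIfTI and table I/O helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def default_affine(voxel_size_mm: float, shape) -> np.ndarray:
    """Axis-aligned affine with the grid center at world origin."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    return aff


def save_volume(
    path: str | Path,
    data: np.ndarray,
    voxel_size_mm: float = 2.0,
    affine: np.ndarray | None = None,
) -> None:
    data = np.asarray(data)
    if affine is None:
        affine = default_affine(voxel_size_mm, data.shape)
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
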