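"""NIfTI volume and CSV lesion-table I/O.

Volumes travel as single-file NIfTI (.nii / .nii.gz): spacing is taken from
the header zooms (mm) and the stored array axis order (x, y, z) is used
as-is. Lesion tables are RFC-4180 CSV with '.' decimal; units are mm, ml
and ASP-percent by column contract, never embedded per cell.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import LesionVOI, VoxelGrid

#: Required columns of a lesion table, in canonical order.
TABLE_COLUMNS = [
    "patient_id",
    "lesion_id",
    "organ",
    "asp_percent",
    "ftv_ml",
    "diameter_baseline_mm",
    "diameter_4m_mm",
    "diameter_12m_mm",
    "true_class",
]

_DIAMETER_COLUMNS = ["diameter_baseline_mm", "diameter_4m_mm", "diameter_12m_mm"]


def read_volume(path: str | os.PathLike) -> VoxelGrid:
    """Read a 3D NIfTI image into a :class:`VoxelGrid` (float64, spacing in mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any((not np.isfinite(s)) or s <= 0 for s in spacing):
        raise ValueError(f"{path}: invalid voxel spacing {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelGrid(values=data.astype(np.float64), spacing_mm=spacing, origin_mm=origin)


def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a grid as NIfTI with a diagonal affine built from spacing/origin."""
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    affine[:3, 3] = grid.origin_mm
    img = nib.Nifti1Image(grid.values.astype(np.float32), affine)
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike, grid_ref: str = "") -> LesionVOI:
    grid = read_volume(path)
    return LesionVOI(mask=grid.values > 0.5, grid_ref=grid_ref)


def write_mask(voi: LesionVOI, spacing_mm, path: str | os.PathLike) -> None:
    write_volume(VoxelGrid(voi.mask.astype(np.float64), spacing_mm), path)


def validate_lesion_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the column contract; returns the table unchanged on success."""
    for col in TABLE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"lesion table is missing required column '{col}'")
    for col in _DIAMETER_COLUMNS + ["ftv_ml"]:
        vals = pd.to_numeric(table[col], errors="coerce")
        if (vals < 0).any():
            bad = table.index[vals < 0].tolist()
            raise ValueError(f"column '{col}' contains negative values at rows {bad}")
    return table


def read_lesion_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a lesion CSV; unknown columns are preserved."""
    table = pd.read_csv(path)
    return validate_lesion_table(table)


def write_lesion_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_lesion_table(table)
    # canonical columns first, extras after, for stable diffs
    extras = [c for c in table.columns if c not in TABLE_COLUMNS]
    table[TABLE_COLUMNS + extras].to_csv(path, index=False)
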