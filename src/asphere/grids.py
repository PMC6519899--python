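"""Voxel-grid containers shared by every stage of the pipeline.

Geometry contract: arrays are indexed (x, y, z); ``spacing_mm`` is the
per-axis voxel edge length in millimetres; voxel coordinates are
voxel-center based, so the world position of index ``(i, j, k)`` is
``origin_mm + index * spacing_mm``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np


@dataclass
class VoxelGrid:
    """A 3D activity image (arbitrary counts) with voxel spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"VoxelGrid requires a 3D array, got {self.values.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive lengths, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid values must be finite")
        if np.any(self.values < 0):
            raise ValueError("VoxelGrid values must be non-negative")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LesionVOI:
    """Binary mask of one lesion's functional active part on a grid."""

    mask: np.ndarray
    grid_ref: str = ""
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("LesionVOI mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_congruent(self, grid: VoxelGrid) -> None:
        if self.mask.shape != grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid shape {grid.shape}"
            )


def split_seed(seed: int, *tags: object) -> np.random.Generator:
    """Derive an independent generator from a master seed and a tag path.

    Every source of randomness in the package flows through this helper so
    that stages are independently reproducible: the same ``(seed, tags)``
    pair always yields the same stream regardless of call order.
    """
    key = [zlib.crc32(str(t).encode()) % (2**31) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))
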