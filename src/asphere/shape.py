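"""Functional tumor volume, surface area, and asphericity of a lesion VOI.

Asphericity (ASP) quantifies how far a 3D volume deviates from a sphere of
equal volume:

    ASP = 100 * ((S^3 / (36 pi V^2))^(1/3) - 1)

with S the surface area and V the volume of the delineated functional
active part. A perfect sphere gives ASP = 0; elongation and lobulation
increase it. In somatostatin-receptor imaging, small ASP (roughly 1-5%)
corresponds to a near-spherical uptake pattern.

Numerical choices:

* V is the voxel count times the voxel volume — this is the "functional
  tumor volume" of a threshold delineation, not a mesh-enclosed volume
  (the latter is exposed in :class:`ShapeMetrics` for diagnostics only).
* S is the area of a sub-voxel-interpolated triangulated iso-surface:
  the binary mask is anti-aliased with a one-voxel Gaussian and the 0.5
  level surface is extracted by marching cubes honoring anisotropic
  spacing. Counting exposed voxel faces would overestimate a sphere's
  area by a roughly constant factor (~1.5), and marching cubes on the raw
  binary mask still by ~9%, biasing ASP upward everywhere; the
  anti-aliased mesh estimator converges to the true area as spacing is
  refined.
* ASP is not clipped at zero: tiny negative values from discretization are
  reported as-is, keeping the estimator unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .grids import LesionVOI, VoxelGrid


@dataclass(frozen=True)
class ShapeMetrics:
    V_ml: float
    S_mm2: float
    H: float
    ASP_percent: float
    n_vertices: int = 0
    n_faces: int = 0
    mesh_volume_ml: float = float("nan")


def functional_volume(voi: LesionVOI, spacing_mm) -> float:
    """Volume in ml: (number of mask voxels) x (voxel volume in mm^3) / 1000."""
    n = voi.n_voxels
    if n == 0:
        raise ValueError("functional_volume: empty mask")
    return n * float(np.prod(spacing_mm)) / 1000.0


#: Gaussian anti-aliasing width (in voxels, per axis) applied to the binary
#: mask before iso-surface extraction. One voxel removes the staircase bias
#: of marching cubes on raw binary data (which overestimates a sphere's
#: area by ~9% at any spacing) while keeping the 0.5 level surface within
#: a voxel of the mask boundary.
ANTIALIAS_SIGMA_VOX = 1.0


def _marching_cubes(voi: LesionVOI, spacing_mm):
    mask = voi.mask
    if voi.n_voxels == 0:
        raise ValueError("surface_area: empty mask")
    # a mask on the array border would yield a clipped (open) surface
    border = (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    if border:
        raise ValueError("surface_area: mask touches the array border; surface would be clipped")
    field = np.pad(mask, 4).astype(np.float64)
    smoothed = ndimage.gaussian_filter(field, sigma=ANTIALIAS_SIGMA_VOX)
    if smoothed.max() <= 0.5:  # mask too small to survive anti-aliasing
        smoothed = field
    verts, faces, _, _ = measure.marching_cubes(
        smoothed, level=0.5, spacing=tuple(float(s) for s in spacing_mm)
    )
    return verts, faces


def surface_area(voi: LesionVOI, spacing_mm) -> float:
    """Area (mm^2) of the interpolated triangle mesh of the mask boundary."""
    verts, faces = _marching_cubes(voi, spacing_mm)
    return float(measure.mesh_surface_area(verts, faces))


def asphericity(S_mm2: float, V_ml: float) -> float:
    """ASP in percent from surface area (mm^2) and volume (ml)."""
    if not S_mm2 > 0:
        raise ValueError(f"asphericity: surface area must be positive, got {S_mm2}")
    if not V_ml > 0:
        raise ValueError(f"asphericity: volume must be positive, got {V_ml}")
    V_mm3 = V_ml * 1000.0
    H = S_mm2**3 / (36.0 * np.pi * V_mm3**2)
    return float(100.0 * (np.cbrt(H) - 1.0))


def measure_voi(voi: LesionVOI, grid: VoxelGrid) -> ShapeMetrics:
    """Compose volume, surface and ASP for one VOI on its grid."""
    voi.check_congruent(grid)
    V_ml = functional_volume(voi, grid.spacing_mm)
    verts, faces = _marching_cubes(voi, grid.spacing_mm)
    S = float(measure.mesh_surface_area(verts, faces))
    V_mm3 = V_ml * 1000.0
    H = S**3 / (36.0 * np.pi * V_mm3**2)
    # signed mesh volume (diagnostic): sum of signed tetrahedra to the origin
    tri = verts[faces]
    mesh_v = abs(float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])))) / 6.0
    return ShapeMetrics(
        V_ml=V_ml,
        S_mm2=S,
        H=float(H),
        ASP_percent=float(100.0 * (np.cbrt(H) - 1.0)),
        n_vertices=len(verts),
        n_faces=len(faces),
        mesh_volume_ml=mesh_v / 1000.0,
    )
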