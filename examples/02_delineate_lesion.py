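"""Delineate a blurred, noisy lesion with the background-adapted threshold.

Simulates a SPECT-like sphere (r = 15 mm, 10:1 contrast, 8 mm PSF, Poisson
counts) and recovers its functional tumor volume from a single seed click.
"""

from asphere.segmentation import DelineationParams, delineate
from asphere.synthetic import PhantomSpec, ShapeSpec, make_phantom

spec = PhantomSpec(
    shape=ShapeSpec("sphere", semi_axes_mm=(15.0, 15.0, 15.0)),
    grid_shape=(72, 72, 72),
    spacing_mm=(2.0, 2.0, 2.0),
    lesion_activity=100.0,
    background_activity=10.0,
    psf_fwhm_mm=8.0,
    noise="poisson",
    seed=7,
)
grid, truth, analytic = make_phantom(spec)

voi = delineate(grid, seed_point=(36, 36, 36), params=DelineationParams(q=0.39))
V = voi.n_voxels * grid.voxel_volume_mm3 / 1000

print(f"true volume      : {analytic['V_ml']:.2f} ml")
print(f"recovered volume : {V:.2f} ml  "
      f"({100 * (V / analytic['V_ml'] - 1):+.1f} %, "
      f"{voi.n_iterations} iterations, converged={voi.converged})")
print("The adaptive threshold T = B + 0.39*(peak - B) adjusts to the local")
print("background, keeping the volume error small despite blur and noise.")
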