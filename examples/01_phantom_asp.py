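"""Measure asphericity of a phantom and compare it with exact geometry.

Builds a prolate-ellipsoid lesion phantom (semi-axes 20 x 10 x 10 mm) on a
1 mm grid, measures its functional volume, mesh surface area and ASP from
the rasterized mask, and prints them next to the closed-form values.
"""

from asphere.shape import measure_voi
from asphere.synthetic import PhantomSpec, ShapeSpec, make_phantom

spec = PhantomSpec(
    shape=ShapeSpec("ellipsoid", semi_axes_mm=(20.0, 10.0, 10.0)),
    grid_shape=(92, 92, 92),
    spacing_mm=(1.0, 1.0, 1.0),
    psf_fwhm_mm=8.0,
)
grid, truth, analytic = make_phantom(spec)
measured = measure_voi(truth, grid)

print(f"analytic: V = {analytic['V_ml']:.2f} ml, S = {analytic['S_mm2']:.0f} mm^2, "
      f"ASP = {analytic['ASP_percent']:.2f} %")
print(f"measured: V = {measured.V_ml:.2f} ml, S = {measured.S_mm2:.0f} mm^2, "
      f"ASP = {measured.ASP_percent:.2f} %")
print("A 2:1 prolate lesion deviates ~8% from a sphere of equal volume; the")
print("mesh estimate tracks the exact value to within the discretization error.")
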