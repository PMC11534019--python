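"""The normal-eye limit: a 24 mm-axial-length sphere.

Builds an analytic spherical eyeball of radius 12 mm (no staphyloma),
runs the full analysis — inscribed-sphere frame, 120° posterior region,
per-point distance D and 3 mm local sphere-fit curvature C — and prints
the seven shape parameters.

For a perfect 24 mm eye every posterior point sits 12 mm from the
pre-elongation center, so D_var (asphericity) is ~0 and C·D_max
(elongation × sharpness) is ~1.  Any real staphyloma pushes both up.
"""

import scleratopo as st

pc, _truth = st.make_surface(st.PhantomSpec(semi_axes=(12.0, 12.0, 12.0)), n_points=20000)
result = st.analyze_surface(pc, anterior_hint=(0, -1, 0))

p = result.parameters
print(f"inscribed sphere radius : {result.frame.sphere_radius:8.3f} mm")
print(f"D_mean  : {p.D_mean:8.4f} mm      (12 = normal globe radius)")
print(f"D_var   : {p.D_var:8.2e} mm^2   (0 = perfectly spherical posterior)")
print(f"C_mean  : {p.C_mean:8.4f} mm^-1   (1/12 = 0.0833 for a normal eye)")
print(f"CD_mean : {p.CD_mean:8.4f}        (~1 for a normal eye)")
print(f"CD_max  : {p.CD_max:8.4f}        (>1 signals elongation + sharp bulge)")
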