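# Methods

## Geometry model

The analysis treats the eyeball as a closed star-shaped surface in world
millimetres. All geometry is done on points mapped through the volume header
affine, so voxel anisotropy and acquisition orientation never reach the
measurement code.

**Coordinate frame.** The pupillary-foveal axis is estimated from the
maximally inscribed sphere: its center must lie on the anatomical axis, and —
crucially for staphylomatous eyes — it is bounded by the equatorial globe,
not the posterior surface, so posterior outpouching cannot skew it. The
inscribed sphere is found as the argmax of the Euclidean distance transform
of the isotropic mask (exact on the grid), then refined to sub-voxel
precision by Nelder–Mead maximization of the minimum distance to the
marching-cubes surface points (a continuous but non-smooth objective; a
1 mm initial simplex avoids premature convergence). The corneal vertex is
the anterior surface point (positive dot product with a user- or
header-supplied anterior hint) farthest from the center. Because the
anterior pole is blunt, the raw argmax over discrete vertices jitters
laterally by up to ~1 mm at 0.5 mm spacing; by default all points within
0.25 mm of the maximal distance are averaged directionally (cap centroid),
which recovers the pole of a symmetric cap essentially exactly and keeps the
axis error of the full pipeline below ~1° on phantoms (`refine_tol=0`
restores the plain argmax with an angle tie-break). The origin of all
distance measurements sits 12 mm posterior to the vertex along the axis —
the center a normal 24 mm eye would have. Eye coordinates are +X temporal
(left eyes mirrored so the convention is laterality-independent), +Y
posterior, +Z completing a right-handed frame.

**Surface extraction.** The binary mask is resampled to isotropic 0.5 mm
(linear interpolation, re-thresholded at 0.5, with cell-aligned sampling so
output samples never land exactly on the ambiguous mid-voxel 0.5-level —
that alignment would otherwise bias the boundary outward by half an output
voxel and inflate volumes by ~4%). It is then Gaussian-smoothed and
triangulated by marching cubes at iso-level 0.5. The smoothing sigma
defaults to 1.0 mm (two voxels): one-voxel smoothing leaves ~0.035 mm RMS
lattice ripple in the surface, which the 95th-percentile curvature
statistics amplify (sphere-limit `CD_max` 1.083 at σ = 0.5 mm vs 1.047 at
σ = 1.0 mm), while the extra shrinkage is only ~0.15 mm on a 12 mm globe —
small against every effect measured here.

**Distance and curvature.** Over the posterior cone of 120° full span about
+Y (apex at the origin — the same point D is measured from), each point gets
`D = ‖p‖` and `C = 1/R_fit`, where `R_fit` is the radius of the sphere
fitted to all surface points within a 3 mm Euclidean ball. Neighbourhoods
are drawn from the full cloud so fits at the region rim are not truncated.
The fit is the linearized (Kåsa) least squares — exact on noiseless
spherical data — followed by one Gauss–Newton step on the geometric
(orthogonal) residuals, on by default because the raw algebraic fit
underestimates the radius of shallow noisy caps by several percent
(measured 11.26 mm vs true 12 on a voxelized sphere; 11.99 with the step).
Degenerate neighbourhoods are flagged, never imputed: fewer than 10
neighbours → missing; rank-deficient (coplanar) or fitted radius beyond
1000 mm → curvature clamped to 1/1000 mm⁻¹ and flagged. Flagged points are
excluded from all downstream statistics.

## Shape parameters

| parameter | units | definition |
|---|---|---|
| D_mean, C_mean | mm, mm⁻¹ | arithmetic means over unflagged posterior points |
| D_max, C_max | mm, mm⁻¹ | 95th percentiles (robust maxima) |
| D_var | mm² | population (1/N) variance of D |
| C·D_mean, C·D_max | — | mean / 95th percentile of the per-point product |

Percentiles interpolate linearly between order statistics (the numpy
default); the percentile rank and variance denominator are configurable.
Both conventions are reporting choices, not inferential ones — D_var is a
shape descriptor, so the population variance is the natural default.
Analytic limits used as oracles: a radius-12 sphere centered at the origin
has D_var = 0 and C·D_mean = C·D_max = 1 exactly; a displaced-but-spherical
posterior keeps D_var small while C·D_max > 1 (pure elongation); a sharp
protrusion raises both.

## Topography maps

Per-point values are binned on a (polar angle from the posterior pole ×
azimuth) grid, 1° cells by default, mean per cell; empty cells are missing
(NaN), never zero. The rendered map shows D and C as two polar panels
(azimuthal-equidistant, pole at center). The projection and cell statistic
are display choices with no effect on the parameters, which are computed
from the raw points.

## ROC statistics

Full AUC uses the Mann–Whitney rank identity with ties counted ½. The
partial AUC integrates the empirical ROC polyline over false-positive rate
0–0.15 (specificity 85–100%) by trapezoids on its vertices and divides by
0.15, so a perfect marker scores 1.0 and the chance diagonal scores 0.075
exactly. Orientation is auto-selected so AUC ≥ 0.5 (the parameters are
directionless); note that this selection biases *chance-level* partial AUC
upward (it takes the better of two noisy directions), so calibration checks
against the 0.075 diagonal use the fixed-orientation mode.

## Synthetic phantoms

Phantoms are star-shaped radial surfaces r(u) = r_ellipsoid(u) +
A·exp(−ψ²/2σ_b²), with ψ the angle to the bump direction — a smooth,
self-intersection-free stand-in for conical protrusions. Defaults per type:
Type 0 (11, 13.5, 11) mm semi-axes, no bump; Type 1 (11, 14.5, 11) with a
polar bump A = 1.5 mm, σ_b = 25°; Type 2 (11, 16, 11) with an off-pole
(25° temporal) bump A = 3 mm, σ_b = 15°. These amplitudes land D_var near
0.7 / 3 / 6 mm² — the range observed across real staphyloma types — and are
test fixtures, not clinical claims. Surfaces are sampled on a Fibonacci
sphere (quasi-uniform, so spherical-cap fraction checks are tight) with
optional seeded Gaussian noise; volumes are voxelized by inside-testing
voxel centers of an axis-aligned world grid against the posed radial model,
so a rotated phantom is genuinely re-discretized. Cohorts jitter semi-axes
±5% and amplitude ±20% and add a small random pose (≤10° rotation, ≤3 mm
shift — supine MRI eyes are roughly but not exactly aligned); everything is
deterministic given the seed.

What the phantoms do **not** emulate: segmentation errors (the masks are
clean by construction), partial-volume/intensity effects, corneal and
anterior-chamber geometry (the anterior surface is a smooth ellipsoid cap),
and real within-type anatomic diversity. Passing tests therefore validate
the geometry pipeline and the discriminative logic of the parameters, not
segmentation robustness or clinical effect sizes.

## Problem sizes and determinism

Default analytic surfaces use 20 000 points; voxelized phantoms use 0.5 mm
grids (~90³ voxels, ~10⁴ surface vertices, ~4×10³ posterior fits per eye —
about a second per eye); the cohort experiment uses 30 eyes (10 per type).
All randomness flows through seeded `numpy` generators; identical inputs
and config reproduce all CSV artifacts bit-identically.

## Known limitations

- **Discretization anisotropy of tail statistics.** The smoothed surface of
  a binary 0.5 mm mask carries a small (~0.01–0.02 mm) orientation-dependent
  radial bias (cubic lattice anisotropy). At the 3 mm fit scale this is
  indistinguishable from curvature, so the *95th-percentile* curvature
  statistics (C_max, C·D_max) and, to a lesser degree, D_var vary by ~2–5%
  when the same shape is re-voxelized under a large rotation. Means
  (D_mean, C_mean, C·D_mean) are stable well below 1%. This is a property
  of binary masks at this spacing — it persists under stronger smoothing,
  mesh smoothing and weighted fitting — and should be kept in mind when
  comparing tail parameters across scan orientations.
- The corneal vertex presumes the mask includes a smooth anterior surface;
  masks truncated anterior to the equator will misplace the axis.
- The 120° cone is measured from the pre-elongation origin, matching the
  definition of D; measuring it from the inscribed-sphere center instead
  would change the region slightly in elongated eyes (configurable).
- Curvature is unsigned; concavities and convexities of equal radius are
  indistinguishable in C (none of the parameters need the sign).
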