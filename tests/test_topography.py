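"""Posterior region selection, D, local sphere-fit curvature, maps."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import least_squares

import scleratopo as st
from scleratopo.errors import InsufficientPointsError
from scleratopo.topography import (
    build_topography_map,
    compute_curvature,
    compute_distance,
    compute_topography,
    fit_local_sphere,
    select_posterior_region,
)


def nls_sphere_oracle(pts):
    """Independent nonlinear least-squares sphere fit (orthogonal residuals)."""
    c0 = pts.mean(axis=0)
    r0 = np.linalg.norm(pts - c0, axis=1).mean()

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    sol = least_squares(resid, np.r_[c0, r0])
    return sol.x[:3], sol.x[3]


class TestPosteriorRegion:
    def test_spherical_cap_fraction(self, sphere_pc):
        """120° cone keeps the spherical-cap fraction (1 − cos 60°)/2 = 0.25."""
        pc, _ = sphere_pc
        region = select_posterior_region(pc, span_deg=120.0)
        frac = len(region) / len(pc)
        assert frac == pytest.approx(0.25, abs=0.01)

    def test_full_span_is_identity(self, sphere_pc):
        pc, _ = sphere_pc
        region = select_posterior_region(pc, span_deg=360.0)
        assert len(region) == len(pc)

    def test_empty_span_raises(self, sphere_pc):
        pc, _ = sphere_pc
        with pytest.raises((InsufficientPointsError, ValueError)):
            select_posterior_region(pc, span_deg=1e-9)

    def test_too_few_points_raises(self):
        pc = st.SurfacePointCloud(np.random.default_rng(0).normal(size=(100, 3)))
        with pytest.raises(InsufficientPointsError):
            select_posterior_region(pc, span_deg=120.0)


class TestDistance:
    def test_distance_is_norm(self):
        assert compute_distance(np.array([[0.0, 18.0, 0.0]]))[0] == pytest.approx(18.0)

    def test_sphere_distance_constant(self, sphere_surface_result):
        D = sphere_surface_result.topography.D
        assert np.allclose(D, 12.0, atol=1e-3)

    def test_bulging_predicate(self):
        topo = st.compute_topography(
            st.SurfacePointCloud(13.0 * st.fibonacci_sphere(4000)), span_deg=120.0
        )
        assert topo.bulging_mask.all()  # 13 mm > 12 mm threshold everywhere


class TestSphereFit:
    def test_exact_sphere_is_recovered(self, rng):
        dirs = st.fibonacci_sphere(500)
        pts = 14.0 * dirs + np.array([1.0, -2.0, 3.0])
        fit = fit_local_sphere(pts)
        assert fit.radius == pytest.approx(14.0, abs=1e-6)
        assert fit.rms_residual < 1e-9

    def test_noisy_sphere_radius(self, rng):
        pts = 14.0 * st.fibonacci_sphere(2000) + rng.normal(0, 0.1, size=(2000, 3))
        fit = fit_local_sphere(pts)
        assert fit.radius == pytest.approx(14.0, abs=0.2)

    def test_too_few_neighbors_raises(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        with pytest.raises(InsufficientPointsError):
            fit_local_sphere(pts)

    def test_near_planar_clamped(self):
        g = np.linspace(-1, 1, 10)
        X, Y = np.meshgrid(g, g)
        plane = np.column_stack([X.ravel(), Y.ravel(), np.zeros(100)])
        fit = fit_local_sphere(plane, radius_cap=1000.0)
        assert fit.clamped and fit.radius == 1000.0

    @pytest.mark.parametrize("shape", ["sphere", "ellipsoid"])
    def test_agrees_with_nonlinear_oracle_noiseless(self, shape):
        """Algebraic fit within 0.1% of the independent NLS oracle on
        noiseless ≤200-point neighbourhoods."""
        if shape == "sphere":
            pts = 12.0 * st.fibonacci_sphere(200)
        else:
            pts = st.fibonacci_sphere(200) * np.array([11.0, 14.0, 11.0])
            pts = pts[pts[:, 1] > 12.0]  # posterior cap neighbourhood
        fit = fit_local_sphere(pts, refine=False)
        _c, r_oracle = nls_sphere_oracle(pts)
        assert fit.radius == pytest.approx(r_oracle, rel=1e-3)


class TestCurvature:
    def test_sphere_curvature_is_reciprocal_radius(self, sphere_pc):
        """C = 1/R within 1e-6 on exact spherical points (R = 12 → 0.0833)."""
        pc, _ = sphere_pc
        region = select_posterior_region(pc)
        C, flagged = compute_curvature(region, neighbor_source=pc.points)
        assert not flagged.any()
        assert np.allclose(C, 1.0 / 12.0, atol=1e-6)

    def test_physiologic_magnitude(self):
        """A 14.3 mm posterior radius gives C ≈ 0.070 mm⁻¹, the magnitude
        reported for real posterior scleras."""
        pc = st.SurfacePointCloud(14.3 * st.fibonacci_sphere(8000))
        region = select_posterior_region(pc)
        C, _ = compute_curvature(region, neighbor_source=pc.points)
        assert np.nanmean(C) == pytest.approx(0.070, abs=0.001)

    def test_ellipsoid_pole_matches_bruteforce_cap_fit(self):
        """At the posterior pole of an ellipsoid, C equals 1/R of the
        best-fit sphere over the 3 mm cap (dense NLS oracle)."""
        pts = st.fibonacci_sphere(60000) * np.array([11.0, 14.0, 11.0])
        pole = np.array([0.0, 14.0, 0.0])
        cap = pts[np.linalg.norm(pts - pole, axis=1) <= 3.0]
        _c, r_oracle = nls_sphere_oracle(cap)
        fit = fit_local_sphere(pts, pole, neighborhood_radius=3.0)
        assert fit.radius == pytest.approx(r_oracle, rel=2e-3)


class TestScalingAndRigidLaws:
    @pytest.mark.parametrize("s", [0.5, 2.0])
    def test_scaling_law(self, s):
        """Scaling points by s about the origin: D → sD, C → C/s, C·D fixed
        (neighbourhood scaled with the geometry)."""
        pts = st.fibonacci_sphere(6000) * np.array([11.0, 14.0, 11.0])
        t0 = compute_topography(st.SurfacePointCloud(pts), neighborhood_mm=3.0)
        t1 = compute_topography(st.SurfacePointCloud(pts * s), neighborhood_mm=3.0 * s)
        assert np.allclose(t1.D, s * t0.D, rtol=1e-9)
        assert np.allclose(t1.C, t0.C / s, rtol=1e-6)
        assert np.allclose(t1.CD, t0.CD, rtol=1e-6)

    def test_rigid_invariance_of_D_and_C(self, rng):
        """D and C are identical (1e-9) when points and frame are moved by
        the same rigid transform."""
        pc, _ = st.make_surface(
            st.PhantomSpec(
                semi_axes=(11.0, 14.5, 11.0), bump_amplitude=1.5, bump_angular_sigma_deg=25.0
            ),
            n_points=8000,
        )
        frame = st.build_eye_frame((0, 0, 0), (0, -14.5, 0))
        pose = st.RigidPose.random(rng)
        moved = st.SurfacePointCloud(pose.apply(pc.points))
        frame_moved = frame.transformed(pose.rotation, pose.translation)
        t0 = compute_topography(st.to_eye_coordinates(pc, frame))
        t1 = compute_topography(st.to_eye_coordinates(moved, frame_moved))
        assert np.allclose(t0.D, t1.D, atol=1e-9)
        assert np.allclose(t0.C, t1.C, atol=1e-9)


class TestTopographyMaps:
    def test_sphere_maps_are_constant(self, sphere_surface_result):
        grid = build_topography_map(sphere_surface_result.topography)
        assert np.nanstd(grid.D) < 0.01
        assert np.nanstd(grid.C) < 1e-4

    def test_central_bump_peaks_at_pole(self):
        """Type-1-like phantom: map maximum of D and C within 10° of the
        posterior pole."""
        pc, _ = st.make_surface(st.DEFAULT_TYPE_SPECS[1], n_points=20000)
        res = st.analyze_surface(pc, anterior_hint=(0, -1, 0))
        grid = build_topography_map(res.topography, grid_res_deg=2.0)
        ip = np.unravel_index(np.nanargmax(grid.D), grid.D.shape)[0]
        assert grid.polar_centers_deg[ip] <= 10.0

    def test_offaxis_bump_location_recovered(self):
        """Type-2-like phantom: the D-map maximum sits off-pole at the polar
        angle the generator's radial model predicts, within 5°."""
        from scleratopo.phantom import _radial

        spec = st.DEFAULT_TYPE_SPECS[2]  # bump 25° off-pole (temporal)
        # analytic expected peak: evaluate D over dense directions from the
        # ground-truth origin and take the argmax polar angle
        truth = st.ground_truth(spec)
        dirs = st.fibonacci_sphere(200000)
        pts = dirs * _radial(spec, dirs)[:, None]
        rel = pts - truth.origin
        D = np.linalg.norm(rel, axis=1)
        post = rel[:, 1] > 0
        i = np.argmax(np.where(post, D, -np.inf))
        expected_polar = np.degrees(np.arccos(rel[i, 1] / D[i]))
        assert expected_polar > 5.0  # genuinely off-pole

        pc, _ = st.make_surface(spec, n_points=20000)
        res = st.analyze_surface(pc, anterior_hint=(0, -1, 0))
        grid = build_topography_map(res.topography, grid_res_deg=2.0)
        ip = np.unravel_index(np.nanargmax(grid.D), grid.D.shape)[0]
        assert grid.polar_centers_deg[ip] == pytest.approx(expected_polar, abs=5.0)

    def test_grid_csv_and_png(self, tmp_path, sphere_surface_result):
        grid = build_topography_map(sphere_surface_result.topography, grid_res_deg=5.0)
        csv = grid.save_csv(tmp_path / "grid.csv")
        assert csv.exists()
        df = grid.to_dataframe()
        assert {"polar_deg", "azimuth_deg", "D_mm", "C_per_mm", "CD", "n"} <= set(df.columns)
        # empty cells are missing, not zero
        assert df.loc[df.n == 0, "D_mm"].isna().all()
        png = st.render_topography_map(grid, tmp_path / "map.png")
        assert png.stat().st_size > 0
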