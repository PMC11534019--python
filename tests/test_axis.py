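"""Pupillary-foveal frame: inscribed sphere, corneal vertex, eye coordinates."""

import dataclasses

import numpy as np
import pytest

import scleratopo as st
from scleratopo.axis import (
    build_eye_frame,
    chebyshev_center,
    find_corneal_vertex,
    find_inscribed_sphere,
    to_eye_coordinates,
)
from scleratopo.errors import DegenerateGeometryError, EmptyForegroundError


def angle_deg(u, v):
    return np.degrees(np.arccos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))


class TestInscribedSphere:
    def test_ball_is_its_own_inscribed_sphere(self, sphere_volume):
        center, radius = find_inscribed_sphere(sphere_volume)
        assert np.linalg.norm(center) <= 0.5
        assert radius == pytest.approx(12.0, abs=0.5)

    def test_prolate_spheroid_radius_is_minor_semi_axis(self, prolate_volume):
        """Analytic oracle: the inscribed ball of a prolate spheroid has the
        minor semi-axis as radius and its center on the long axis."""
        center, radius = find_inscribed_sphere(prolate_volume)
        assert radius == pytest.approx(11.0, abs=0.5)
        assert abs(center[0]) < 0.5 and abs(center[2]) < 0.5

    def test_edt_maximum_agrees_with_refined_center(self, prolate_volume):
        """Brute-force EDT argmax (no refinement) and the continuous
        refinement land on the same center within a voxel."""
        c0, _ = find_inscribed_sphere(prolate_volume, refine=False)
        c1, _ = find_inscribed_sphere(prolate_volume, refine=True)
        assert np.linalg.norm(c1 - c0) <= 0.5 * np.sqrt(3)

    def test_posterior_bump_does_not_move_the_sphere(self):
        """Adding posterior material only adds volume outside the inscribed
        ball, so the EDT maximum is unchanged."""
        base = st.PhantomSpec(semi_axes=(11.0, 14.0, 11.0))
        bumped = dataclasses.replace(
            base, bump_amplitude=3.0, bump_direction=(0.0, 1.0, 0.0), bump_angular_sigma_deg=20.0
        )
        c0, r0 = find_inscribed_sphere(st.make_volume(base))
        c1, r1 = find_inscribed_sphere(st.make_volume(bumped))
        assert abs(r1 - r0) <= 0.25
        assert np.linalg.norm(c1 - c0) <= 0.5

    def test_degenerate_and_empty_masks(self):
        thin = np.zeros((20, 20, 20), np.uint8)
        thin[5:15, 9:11, 5:15] = 1
        vol = st.LabeledVolume(thin, (0.5,) * 3, np.diag([0.5, 0.5, 0.5, 1.0]))
        with pytest.raises(DegenerateGeometryError):
            find_inscribed_sphere(vol)
        empty = st.LabeledVolume(np.zeros((8, 8, 8), np.uint8), (0.5,) * 3, np.eye(4))
        with pytest.raises(EmptyForegroundError):
            find_inscribed_sphere(empty)


class TestCornealVertex:
    def test_sphere_vertex_in_hint_hemisphere(self, sphere_pc):
        pc, _ = sphere_pc
        v = find_corneal_vertex(pc, np.zeros(3), (0.0, -1.0, 0.0))
        assert np.linalg.norm(v) == pytest.approx(12.0, abs=0.5)
        assert v[1] < 0

    def test_ellipsoid_anterior_pole(self):
        pc, _ = st.make_surface(st.PhantomSpec(semi_axes=(11.0, 14.0, 11.0)), n_points=20000)
        v = find_corneal_vertex(pc, np.zeros(3), (0.0, -1.0, 0.0))
        assert np.linalg.norm(v - np.array([0.0, -14.0, 0.0])) < 1.0

    def test_orthogonal_hint_tiebreak_is_deterministic(self, sphere_pc):
        pc, _ = sphere_pc
        v1 = find_corneal_vertex(pc, np.zeros(3), (1.0, 0.0, 0.0), refine_tol=0.0)
        v2 = find_corneal_vertex(pc, np.zeros(3), (1.0, 0.0, 0.0), refine_tol=0.0)
        assert np.array_equal(v1, v2)
        assert np.linalg.norm(v1) == pytest.approx(12.0, abs=0.1)

    def test_no_anterior_points_raises(self, sphere_pc):
        pc, _ = sphere_pc
        posterior_only = st.SurfacePointCloud(pc.points[pc.points[:, 1] > 0])
        with pytest.raises(DegenerateGeometryError):
            find_corneal_vertex(posterior_only, np.zeros(3), (0.0, -1.0, 0.0))


class TestEyeFrame:
    def test_axis_origin_construction(self):
        fr = build_eye_frame(center=(0, 0, 0), vertex=(0, -12, 0), offset=12.0)
        assert np.allclose(fr.axis, [0, 1, 0])
        assert np.allclose(fr.origin, [0, 0, 0])
        assert np.linalg.norm(fr.origin - fr.corneal_vertex) == pytest.approx(12.0)
        # right-handed orthonormal basis
        R = fr.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_offset_always_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c, v = rng.normal(size=3) * 5, rng.normal(size=3) * 5 + 20
            fr = build_eye_frame(c, v, offset=12.0)
            assert np.linalg.norm(fr.origin - fr.corneal_vertex) == pytest.approx(12.0, abs=1e-12)

    def test_vertex_equals_center_raises(self):
        with pytest.raises(DegenerateGeometryError):
            build_eye_frame((0, 0, 0), (0.1, 0, 0))

    def test_frame_json_roundtrip(self, tmp_path):
        fr = build_eye_frame((1, 2, 3), (1, -11, 3), laterality="OS", sphere_radius=10.5)
        path = fr.save(tmp_path / "frame.json")
        back = st.EyeFrame.load(path)
        assert np.allclose(back.origin, fr.origin)
        assert back.laterality == "OS"


class TestEyeCoordinates:
    def test_aligned_input_is_identity(self, sphere_pc):
        pc, _ = sphere_pc
        fr = build_eye_frame((0, 0, 0), (0, -12, 0))
        out = to_eye_coordinates(pc, fr)
        assert np.allclose(out.points, pc.points, atol=1e-12)

    def test_pairwise_distances_preserved(self, rng):
        pts = rng.normal(size=(100, 3)) * 10
        pc = st.SurfacePointCloud(pts)
        fr = build_eye_frame((3, 1, -2), (9, 8, 7), x_hint=(0, 0, 1), laterality="OS")
        out = to_eye_coordinates(pc, fr)
        d0 = np.linalg.norm(pts[:50] - pts[50:], axis=1)
        d1 = np.linalg.norm(out.points[:50] - out.points[50:], axis=1)
        assert np.allclose(d0, d1, atol=1e-9)
        assert out.meta["mirrored"] is True

    def test_frame_construction_deterministic(self, sphere_volume):
        c1, r1 = find_inscribed_sphere(sphere_volume)
        c2, r2 = find_inscribed_sphere(sphere_volume)
        assert np.array_equal(c1, c2) and r1 == r2


class TestAxisRecovery:
    def test_recovery_under_random_rigid_poses(self):
        """Recovered pupillary-foveal axis within 3° of ground truth for
        Type 0/1 phantoms, 5° for Type 2, under random rigid poses."""
        rng = np.random.default_rng(11)
        tol = {0: 3.0, 1: 3.0, 2: 5.0}
        for label, base in st.DEFAULT_TYPE_SPECS.items():
            pose = st.RigidPose.random(rng, max_angle_deg=180.0, max_shift_mm=5.0)
            spec = dataclasses.replace(base, rigid_pose=pose)
            truth = st.ground_truth(spec)
            res = st.analyze_volume(
                st.make_volume(spec), anterior_hint=tuple(truth.anterior_hint_world)
            )
            assert angle_deg(res.frame.axis, truth.axis_world) <= tol[label]

    def test_axis_insensitive_to_posterior_bump(self):
        """A ≤4 mm posterior bump moves the recovered axis by ≤1.5° — the
        inscribed-sphere construction ignores posterior irregularity."""
        base = st.PhantomSpec(semi_axes=(11.0, 14.0, 11.0))
        res0 = st.analyze_volume(st.make_volume(base), anterior_hint=(0, -1, 0))
        for amp in (2.0, 4.0):
            bumped = dataclasses.replace(
                base,
                bump_amplitude=amp,
                bump_direction=(np.sin(0.35), np.cos(0.35), 0.0),
                bump_angular_sigma_deg=20.0,
            )
            res = st.analyze_volume(st.make_volume(bumped), anterior_hint=(0, -1, 0))
            assert angle_deg(res.frame.axis, res0.frame.axis) <= 1.5

    def test_chebyshev_center_on_exact_sphere(self, sphere_pc):
        pc, _ = sphere_pc
        c, r = chebyshev_center(pc.points)
        assert np.linalg.norm(c) < 1e-4
        assert r == pytest.approx(12.0, abs=1e-3)
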