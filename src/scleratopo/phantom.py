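"""Synthetic eyeball phantoms with analytic ground truth.

The generator emulates the three qualitative posterior eye-shape classes
used in staphyloma grading:

* **Type 0** — elongated globe, nasal/temporal symmetry, no apparent
  posterior protrusion (prolate ellipsoid).
* **Type 1** — elongated globe with a symmetric conical posterior protrusion
  (axisymmetric bump at the posterior pole).
* **Type 2** — elongated globe with a sharp nasal or temporal protrusion
  (off-axis bump).

Shapes follow a star-shaped radial model about the ellipsoid center:

    r(u) = r_ellipsoid(u) + A · exp(−ψ(u)² / (2 σ_b²))

where ``u`` is a unit direction, ``ψ(u)`` its angle to the bump direction,
``A`` the bump amplitude (mm) and ``σ_b`` the angular width.  A Gaussian
angular bump is a smooth, self-intersection-free stand-in for a conical
protrusion.  Surfaces are sampled quasi-uniformly (Fibonacci sphere) with
optional Gaussian coordinate noise; volumes are voxelized by inside-testing
voxel centers against the radial model.  Every phantom carries its analytic
axis, corneal vertex, origin and per-direction distances, so downstream
estimates can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import LabeledVolume, SurfacePointCloud

__all__ = [
    "RigidPose",
    "PhantomSpec",
    "PhantomTruth",
    "CohortEye",
    "DEFAULT_TYPE_SPECS",
    "fibonacci_sphere",
    "make_surface",
    "make_volume",
    "make_cohort",
    "ground_truth",
]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit directions (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), z, rho * np.sin(phi)])


@dataclass(frozen=True, eq=False)
class RigidPose:
    """Rotation + translation applied to the phantom's world placement."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RigidPose):
            return NotImplemented
        return np.array_equal(self.rotation, other.rotation) and np.array_equal(
            self.translation, other.translation
        )

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls()

    @classmethod
    def random(
        cls, rng: np.random.Generator, max_angle_deg: float = 180.0, max_shift_mm: float = 5.0
    ) -> "RigidPose":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(0, max_angle_deg))
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        t = rng.uniform(-max_shift_mm, max_shift_mm, size=3)
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def apply_vector(self, v: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(v, dtype=float)

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.translation) @ self.rotation


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic eyeball.

    Local frame: ellipsoid center at the origin, +Y posterior, −Y anterior
    (cornea), +X temporal, +Z superior.  ``rigid_pose`` moves the phantom
    into the world frame last.
    """

    semi_axes: tuple = (11.0, 13.5, 11.0)
    bump_amplitude: float = 0.0
    bump_direction: tuple = (0.0, 1.0, 0.0)
    bump_angular_sigma_deg: float = 25.0
    noise_sigma: float = 0.0
    rigid_pose: RigidPose = field(default_factory=RigidPose.identity)
    voxel_spacing: float = 0.5
    seed: int = 0
    laterality: str = "OD"

    def __post_init__(self):
        ax = np.asarray(self.semi_axes, dtype=float)
        if not np.all(ax > 0):
            raise ValueError("semi_axes must be strictly positive")
        if self.bump_amplitude < 0:
            raise ValueError("bump_amplitude must be >= 0")
        if self.bump_amplitude > 0 and self.bump_angular_sigma_deg <= 0:
            raise ValueError("bump_angular_sigma_deg must be > 0 when a bump is present")
        if self.bump_amplitude > 0.5 * float(ax.min()):
            raise ValueError(
                f"bump amplitude {self.bump_amplitude} mm exceeds half the smallest "
                f"semi-axis ({ax.min()} mm); surface would be degenerate"
            )


def _radial(spec: PhantomSpec, dirs: np.ndarray) -> np.ndarray:
    """Radius of the phantom surface along unit directions (local frame)."""
    a, b, c = spec.semi_axes
    u = np.asarray(dirs, dtype=float)
    r = 1.0 / np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2)
    if spec.bump_amplitude > 0:
        bd = np.asarray(spec.bump_direction, dtype=float)
        bd = bd / np.linalg.norm(bd)
        psi = np.arccos(np.clip(u @ bd, -1.0, 1.0))
        sigma = np.deg2rad(spec.bump_angular_sigma_deg)
        r = r + spec.bump_amplitude * np.exp(-(psi**2) / (2.0 * sigma**2))
    return r


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth in the local frame, plus the world pose."""

    axis: np.ndarray
    vertex: np.ndarray
    origin: np.ndarray
    center: np.ndarray
    pose: RigidPose
    D: Optional[np.ndarray] = None  # per sampled direction, before noise

    @property
    def axis_world(self) -> np.ndarray:
        return self.pose.apply_vector(self.axis)

    @property
    def vertex_world(self) -> np.ndarray:
        return self.pose.apply(self.vertex[None])[0]

    @property
    def origin_world(self) -> np.ndarray:
        return self.pose.apply(self.origin[None])[0]

    @property
    def anterior_hint_world(self) -> np.ndarray:
        return -self.axis_world


def ground_truth(spec: PhantomSpec, offset_mm: float = 12.0) -> PhantomTruth:
    """Analytic axis/vertex/origin of a phantom (no sampling involved)."""
    anterior = np.array([0.0, -1.0, 0.0])
    r_ant = float(_radial(spec, anterior[None])[0])
    vertex = r_ant * anterior
    axis = np.array([0.0, 1.0, 0.0])
    origin = vertex + offset_mm * axis
    return PhantomTruth(
        axis=axis, vertex=vertex, origin=origin, center=np.zeros(3), pose=spec.rigid_pose
    )


def make_surface(
    spec: PhantomSpec, n_points: int = 20000, offset_mm: float = 12.0
) -> tuple[SurfacePointCloud, PhantomTruth]:
    """Sample the phantom surface; return the (posed) cloud and ground truth.

    Noise (``spec.noise_sigma``, mm, seeded by ``spec.seed``) is added to the
    coordinates before the rigid pose; the analytic per-point distances in
    the truth refer to the noise-free surface.
    """
    dirs = fibonacci_sphere(int(n_points))
    r = _radial(spec, dirs)
    pts = dirs * r[:, None]
    truth = ground_truth(spec, offset_mm)
    D_true = np.linalg.norm(pts - truth.origin, axis=1)
    truth = replace(truth, D=D_true)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    world = spec.rigid_pose.apply(pts)
    pc = SurfacePointCloud(
        world,
        meta={
            "source": "phantom",
            "sigma_mm": 0.0,
            "noise_sigma_mm": float(spec.noise_sigma),
            "laterality": spec.laterality,
            "seed": int(spec.seed),
        },
    )
    return pc, truth


def make_volume(
    spec: PhantomSpec,
    fov_mm: float = 46.0,
    spacing=None,
    encode_pose_in_affine: bool = False,
) -> LabeledVolume:
    """Voxelize the phantom at ``spec.voxel_spacing`` (or per-axis ``spacing``).

    By default the posed phantom is sampled on an axis-aligned world grid
    centered on the phantom, so a rotated phantom is genuinely re-discretized
    (rigid-invariance tests exercise real resampling).  With
    ``encode_pose_in_affine=True`` the voxel grid stays in the local frame
    and the pose is stored in the header affine instead.  ``spacing`` may be
    a scalar or a per-axis triple, e.g. (0.5, 0.5, 1.0) to emulate thick MRI
    slices that need resampling.
    """
    r_max = float(np.max(spec.semi_axes)) + spec.bump_amplitude
    if 2.0 * r_max + 2.0 > fov_mm:
        raise ValueError(f"phantom (max radius {r_max:.1f} mm) exceeds the {fov_mm} mm field of view")
    s = np.broadcast_to(
        np.asarray(spec.voxel_spacing if spacing is None else spacing, dtype=float), (3,)
    ).astype(float)
    n = np.ceil(fov_mm / s).astype(int)
    half = (n - 1) / 2.0
    pose = spec.rigid_pose
    ijk = np.stack(
        np.meshgrid(*(np.arange(ni) for ni in n), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    local_grid = (ijk - half) * s
    if encode_pose_in_affine:
        q = local_grid
        affine = np.eye(4)
        affine[:3, :3] = pose.rotation @ np.diag(s)
        affine[:3, 3] = pose.apply((-half * s)[None])[0]
    else:
        world = local_grid + pose.translation
        q = pose.inverse_apply(world)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(s)
        affine[:3, 3] = pose.translation - half * s
    norms = np.linalg.norm(q, axis=1)
    dirs = q / np.where(norms == 0, 1.0, norms)[:, None]
    r = _radial(spec, dirs)
    inside = (norms <= r).reshape(tuple(n))
    return LabeledVolume(inside.astype(np.uint8), s, affine)


DEFAULT_TYPE_SPECS: dict[int, PhantomSpec] = {
    0: PhantomSpec(semi_axes=(11.0, 13.5, 11.0), bump_amplitude=0.0),
    1: PhantomSpec(
        semi_axes=(11.0, 14.5, 11.0),
        bump_amplitude=1.5,
        bump_direction=(0.0, 1.0, 0.0),
        bump_angular_sigma_deg=25.0,
    ),
    2: PhantomSpec(
        semi_axes=(11.0, 16.0, 11.0),
        bump_amplitude=3.0,
        # 25° temporal of the posterior pole
        bump_direction=(np.sin(np.deg2rad(25.0)), np.cos(np.deg2rad(25.0)), 0.0),
        bump_angular_sigma_deg=15.0,
    ),
}


@dataclass(frozen=True)
class CohortEye:
    eye_id: str
    type_label: int
    spec: PhantomSpec
    volume: Optional[LabeledVolume]

    @property
    def truth(self) -> PhantomTruth:
        return ground_truth(self.spec)


def make_cohort(
    n_per_type: int = 10,
    type_specs: Optional[dict[int, PhantomSpec]] = None,
    seed: int = 42,
    voxel_spacing: float = 0.5,
    make_volumes: bool = True,
    max_pose_angle_deg: float = 10.0,
    max_pose_shift_mm: float = 3.0,
) -> list[CohortEye]:
    """Seeded cohort of phantoms with within-type variability.

    Per-eye jitter: semi-axes ±5%, bump amplitude ±20% (uniform), plus a
    small random rigid pose (rotation ≤ ``max_pose_angle_deg``, shift ≤
    ``max_pose_shift_mm`` — supine MRI eyes are roughly but not exactly
    aligned with the scanner).  Deterministic given ``seed``; labels are
    balanced by construction.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    specs = dict(DEFAULT_TYPE_SPECS if type_specs is None else type_specs)
    rng = np.random.default_rng(seed)
    cohort: list[CohortEye] = []
    for label in sorted(specs):
        base = specs[label]
        for i in range(n_per_type):
            axes = np.asarray(base.semi_axes) * rng.uniform(0.95, 1.05, size=3)
            amp = base.bump_amplitude * rng.uniform(0.8, 1.2)
            pose = RigidPose.random(rng, max_pose_angle_deg, max_pose_shift_mm)
            spec = replace(
                base,
                semi_axes=tuple(axes),
                bump_amplitude=float(amp),
                rigid_pose=pose,
                voxel_spacing=voxel_spacing,
                seed=int(rng.integers(2**31)),
            )
            vol = make_volume(spec) if make_volumes else None
            cohort.append(CohortEye(f"type{label}_{i:02d}", label, spec, vol))
    return cohort
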