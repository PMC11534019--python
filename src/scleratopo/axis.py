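"""Pupillary-foveal coordinate frame from the maximally inscribed sphere.

The antero-posterior axis of a highly myopic eye cannot be taken from the
scanner axes (eyes are closed during MRI, gaze is uncontrolled) nor from a
global surface fit (a posterior staphyloma would skew it).  Instead the
largest sphere fully inscribed in the eyeball is found — its center is
insensitive to posterior outpouching because the inscribed sphere is limited
by the equatorial globe, not the posterior bulge — and the corneal vertex is
taken as the anterior surface point farthest from that center.  The line
vertex→center is the pupillary-foveal axis, and the origin of all distance
measurements (the "hypothetical pre-elongation eye center") is placed a fixed
offset (default 12 mm, half a normal 24 mm axial length) posterior to the
vertex along that axis.

Eye coordinates: +X temporal (left eyes mirrored so the convention holds for
both lateralities), +Y posterior along the axis, +Z completing a right-handed
frame (infero-superior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, EmptyForegroundError
from .io import LabeledVolume, SurfacePointCloud, extract_surface

__all__ = [
    "EyeFrame",
    "find_inscribed_sphere",
    "chebyshev_center",
    "find_corneal_vertex",
    "build_eye_frame",
    "to_eye_coordinates",
]


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


@dataclass(frozen=True)
class EyeFrame:
    """Rigid pupillary-foveal frame.

    ``axis`` points from the corneal vertex toward the posterior pole;
    ``origin = corneal_vertex + offset * axis`` exactly by construction.
    """

    sphere_center: np.ndarray
    sphere_radius: float
    corneal_vertex: np.ndarray
    axis: np.ndarray
    origin: np.ndarray
    x_axis: np.ndarray
    z_axis: np.ndarray
    offset: float = 12.0
    laterality: str = "OD"

    @property
    def rotation(self) -> np.ndarray:
        """World→eye rotation matrix (rows are the eye basis vectors)."""
        return np.vstack([self.x_axis, self.axis, self.z_axis])

    def to_dict(self) -> dict:
        return {
            "sphere_center_mm": list(map(float, self.sphere_center)),
            "sphere_radius_mm": float(self.sphere_radius),
            "corneal_vertex_mm": list(map(float, self.corneal_vertex)),
            "axis": list(map(float, self.axis)),
            "origin_mm": list(map(float, self.origin)),
            "x_axis": list(map(float, self.x_axis)),
            "z_axis": list(map(float, self.z_axis)),
            "offset_mm": float(self.offset),
            "laterality": self.laterality,
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "EyeFrame":
        return cls(
            sphere_center=np.asarray(d["sphere_center_mm"], dtype=float),
            sphere_radius=float(d["sphere_radius_mm"]),
            corneal_vertex=np.asarray(d["corneal_vertex_mm"], dtype=float),
            axis=np.asarray(d["axis"], dtype=float),
            origin=np.asarray(d["origin_mm"], dtype=float),
            x_axis=np.asarray(d["x_axis"], dtype=float),
            z_axis=np.asarray(d["z_axis"], dtype=float),
            offset=float(d["offset_mm"]),
            laterality=d.get("laterality", "OD"),
        )

    @classmethod
    def load(cls, path) -> "EyeFrame":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "EyeFrame":
        """The same frame after a rigid world transform p → R p + t.

        Applying the identical transform to a point cloud and its frame
        leaves all eye-coordinate quantities (D, C, the parameters) exactly
        invariant.
        """
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        return EyeFrame(
            sphere_center=R @ self.sphere_center + t,
            sphere_radius=self.sphere_radius,
            corneal_vertex=R @ self.corneal_vertex + t,
            axis=R @ self.axis,
            origin=R @ self.origin + t,
            x_axis=R @ self.x_axis,
            z_axis=R @ self.z_axis,
            offset=self.offset,
            laterality=self.laterality,
        )


def chebyshev_center(
    points: np.ndarray, x0: Optional[np.ndarray] = None, simplex_scale_mm: float = 1.0
) -> tuple[np.ndarray, float]:
    """Center maximizing the minimum distance to the given surface points.

    For a star-shaped closed surface sampled densely enough this is the
    center of the maximally inscribed sphere.  Nelder–Mead is used because
    the objective (a min over points) is continuous but not smooth.
    Deterministic given identical inputs.
    """
    points = np.asarray(points, dtype=float)
    tree = cKDTree(points)
    if x0 is None:
        x0 = points.mean(axis=0)
    x0 = np.asarray(x0, dtype=float).reshape(3)

    def neg_min_dist(c):
        return -tree.query(c)[0]

    simplex = np.vstack([x0, x0 + simplex_scale_mm * np.eye(3)])
    res = minimize(
        neg_min_dist,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": 1e-7,
            "fatol": 1e-10,
            "maxiter": 4000,
            "maxfev": 8000,
        },
    )
    return res.x, float(-res.fun)


def find_inscribed_sphere(
    vol: LabeledVolume, refine: bool = True
) -> tuple[np.ndarray, float]:
    """Center and radius (mm) of the largest ball inside the foreground.

    The Euclidean distance transform of the mask gives the exact grid-level
    solution (its argmax); a continuous Nelder–Mead refinement against the
    marching-cubes surface point k-d tree brings the center to sub-voxel
    precision.  The returned radius is the minimum distance from the refined
    center to any surface point.
    """
    mask = vol.voxels > 0
    if not mask.any():
        raise EmptyForegroundError("empty mask")
    edt = ndimage.distance_transform_edt(mask, sampling=vol.spacing)
    idx = np.unravel_index(int(np.argmax(edt)), edt.shape)
    r0 = float(edt[idx])
    if r0 < 2.0 * float(np.max(vol.spacing)):
        raise DegenerateGeometryError(
            f"inscribed sphere radius {r0:.2f} mm < 2 voxels — mask too thin"
        )
    center = vol.voxel_to_world(np.asarray(idx, dtype=float))
    if not refine:
        return np.asarray(center, dtype=float), r0
    surface = extract_surface(vol, sigma=0.0)
    center, radius = chebyshev_center(
        surface.points, x0=center, simplex_scale_mm=float(vol.spacing[0])
    )
    return center, radius


def find_corneal_vertex(
    pc: SurfacePointCloud,
    center: Sequence[float],
    anterior_hint: Sequence[float],
    refine_tol: float = 0.25,
) -> np.ndarray:
    """Anterior surface point most distant from the inscribed-sphere center.

    Only points in the anterior hemisphere (positive dot product with
    ``anterior_hint``) are considered.  With ``refine_tol > 0`` (default
    0.25 mm) all points within that distance of the maximum are averaged
    directionally, which localizes the vertex of a blunt anterior pole far
    better than a raw argmax over discretized vertices; ``refine_tol=0``
    returns the literal argmax with ties broken by smallest angle to the
    hint, which makes the result deterministic on perfectly symmetric input.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    hint = _unit(anterior_hint)
    rel = pc.points - center
    anterior = rel @ hint > 0
    if not anterior.any():
        raise DegenerateGeometryError("no surface points in the anterior hemisphere")
    rel = rel[anterior]
    dist = np.linalg.norm(rel, axis=1)
    dmax = float(dist.max())
    if refine_tol > 0:
        band = dist >= dmax - refine_tol
        mean_dir = rel[band].mean(axis=0)
        u = _unit(mean_dir) if np.linalg.norm(mean_dir) > 1e-12 else hint
        return center + float(dist[band].mean()) * u
    # argmax with angle tie-break
    tie = dist >= dmax - 1e-9
    cand = rel[tie]
    cosang = (cand @ hint) / np.linalg.norm(cand, axis=1)
    best = int(np.argmax(cosang))
    return center + cand[best]


def build_eye_frame(
    center: Sequence[float],
    vertex: Sequence[float],
    offset: float = 12.0,
    x_hint: Sequence[float] = (1.0, 0.0, 0.0),
    laterality: str = "OD",
    sphere_radius: float = np.nan,
) -> EyeFrame:
    """Complete the rigid eye frame from inscribed center and corneal vertex.

    ``axis`` = unit(center − vertex); ``origin`` = vertex + offset·axis.
    X is the naso-temporal hint projected orthogonal to the axis; Z = X × axis
    completes a right-handed basis.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    vertex = np.asarray(vertex, dtype=float).reshape(3)
    sep = np.linalg.norm(center - vertex)
    if sep < 1.0:
        raise DegenerateGeometryError(
            f"corneal vertex within {sep:.2f} mm of sphere center — degenerate geometry"
        )
    axis = (center - vertex) / sep
    origin = vertex + float(offset) * axis
    x_hint = np.asarray(x_hint, dtype=float).reshape(3)
    x = x_hint - (x_hint @ axis) * axis
    if np.linalg.norm(x) < 1e-6:
        # hint parallel to the axis: pick any orthogonal direction
        fallback = np.eye(3)[int(np.argmin(np.abs(axis)))]
        x = fallback - (fallback @ axis) * axis
    x = _unit(x)
    z = np.cross(x, axis)
    return EyeFrame(
        sphere_center=center,
        sphere_radius=float(sphere_radius),
        corneal_vertex=vertex,
        axis=axis,
        origin=origin,
        x_axis=x,
        z_axis=z,
        offset=float(offset),
        laterality=laterality,
    )


def to_eye_coordinates(
    pc: SurfacePointCloud, frame: EyeFrame, mirror_left: bool = True
) -> SurfacePointCloud:
    """Rigidly transform a point cloud into eye coordinates.

    The frame origin maps to (0,0,0) and the pupillary-foveal axis to +Y
    (posterior positive).  Left eyes (laterality "OS") are mirrored in X by
    default so +X is temporal for every eye; the chirality flip is recorded
    in ``meta['mirrored']``.
    """
    rot = frame.rotation
    pts = (pc.points - frame.origin) @ rot.T
    normals = None if pc.normals is None else pc.normals @ rot.T
    mirrored = frame.laterality.upper() == "OS" and mirror_left
    if mirrored:
        pts = pts * np.array([-1.0, 1.0, 1.0])
        if normals is not None:
            normals = normals * np.array([-1.0, 1.0, 1.0])
    meta = dict(pc.meta)
    meta.update({"frame": "eye", "laterality": frame.laterality, "mirrored": bool(mirrored)})
    return SurfacePointCloud(pts, normals, meta)
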