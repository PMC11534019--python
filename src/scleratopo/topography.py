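"""Posterior scleral topography: per-point distance D and local curvature C.

Working in eye coordinates (origin at the hypothetical pre-elongation eye
center, +Y posterior), the posterior region spanning a 120° cone about +Y is
selected, and two quantities are computed at each surface point:

* ``D`` — Euclidean distance (mm) from the point to the origin.  For a
  normal ~24 mm eye D ≈ 12 mm everywhere; D > 12 mm flags elongation or
  bulging.
* ``C`` — unsigned local curvature (mm⁻¹), the reciprocal radius of the
  least-squares sphere fitted to all surface points within a 3 mm Euclidean
  ball of the point.  A sharp protrusion raises C locally.

Their product C·D is dimensionless and ≈ 1 for a normal eye; elongation
amplifies D while a sharp staphyloma edge amplifies C, so C·D highlights
combined severity.  The per-point values are binned onto an
azimuthal-equidistant grid (polar angle from the posterior pole × azimuth)
for display, analogous to a corneal topography map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InsufficientPointsError
from .io import SurfacePointCloud

__all__ = [
    "SphereFit",
    "TopographyResult",
    "TopographyGrid",
    "select_posterior_region",
    "posterior_mask",
    "compute_distance",
    "fit_local_sphere",
    "compute_curvature",
    "compute_topography",
    "build_topography_map",
    "render_topography_map",
]


def posterior_mask(points: np.ndarray, span_deg: float = 120.0) -> np.ndarray:
    """Boolean mask of points within span/2 of the posterior (+Y) direction.

    The cone apex is the eye-frame origin (the pre-elongation center), the
    same point D is measured from.
    """
    if span_deg <= 0:
        raise ValueError("span_deg must be > 0")
    pts = np.asarray(points, dtype=float)
    norms = np.linalg.norm(pts, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    cosang = pts[:, 1] / norms
    return cosang >= np.cos(np.deg2rad(span_deg / 2.0))


def select_posterior_region(
    pc: SurfacePointCloud, span_deg: float = 120.0, min_points: int = 200
) -> SurfacePointCloud:
    """Keep the points inside the posterior cone (default 120° full span)."""
    keep = posterior_mask(pc.points, span_deg)
    n = int(keep.sum())
    if n < min_points:
        raise InsufficientPointsError(
            f"only {n} points in the {span_deg:.0f}° posterior region (need {min_points})"
        )
    normals = None if pc.normals is None else pc.normals[keep]
    meta = dict(pc.meta)
    meta["span_deg"] = float(span_deg)
    return SurfacePointCloud(pc.points[keep], normals, meta)


def compute_distance(points: np.ndarray) -> np.ndarray:
    """D per point: distance (mm) to the eye-frame origin."""
    return np.linalg.norm(np.asarray(points, dtype=float), axis=1)


@dataclass(frozen=True)
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float
    n_neighbors: int
    clamped: bool = False


def _algebraic_sphere(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Linearized least-squares sphere: minimize ||p|^2 - 2 c·p - d| over c, d.

    Raises LinAlgError for degenerate neighbourhoods — exactly coplanar
    points make the design matrix rank-deficient (no finite sphere).
    """
    A = np.hstack([2.0 * pts, np.ones((pts.shape[0], 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _res, rank, _sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise np.linalg.LinAlgError("coplanar neighborhood: sphere fit is degenerate")
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0:
        raise np.linalg.LinAlgError("degenerate sphere fit")
    return c, float(np.sqrt(r2))


def _gauss_newton_step(pts: np.ndarray, c: np.ndarray, r: float) -> tuple[np.ndarray, float]:
    diff = pts - c
    d = np.linalg.norm(diff, axis=1)
    d = np.where(d == 0, 1e-12, d)
    res = d - r
    J = np.hstack([-diff / d[:, None], -np.ones((pts.shape[0], 1))])
    step, *_ = np.linalg.lstsq(J, -res, rcond=None)
    return c + step[:3], r + float(step[3])


def fit_local_sphere(
    points: np.ndarray,
    center_point: Optional[np.ndarray] = None,
    neighborhood_radius: float = 3.0,
    min_neighbors: int = 10,
    radius_cap: float = 1000.0,
    refine: bool = True,
    tree: Optional[cKDTree] = None,
) -> SphereFit:
    """Fit a sphere to the surface points near ``center_point``.

    If ``center_point`` is None the whole point set is fitted.  The algebraic
    (linearized) least-squares fit is exact on noiseless spherical data but
    underestimates the radius on shallow noisy caps (the classic Kåsa bias),
    so one Gauss-Newton step refining the geometric (orthogonal) solution is
    applied by default; ``refine=False`` gives the raw algebraic fit.  Near-planar neighbourhoods whose fitted radius exceeds
    ``radius_cap`` are clamped to the cap and flagged.
    """
    points = np.asarray(points, dtype=float)
    if center_point is not None:
        if tree is None:
            tree = cKDTree(points)
        idx = tree.query_ball_point(np.asarray(center_point, dtype=float), neighborhood_radius)
        nbrs = points[idx]
    else:
        nbrs = points
    n = nbrs.shape[0]
    if n < min_neighbors:
        raise InsufficientPointsError(
            f"{n} neighbors within {neighborhood_radius} mm (need {min_neighbors})"
        )
    try:
        c, r = _algebraic_sphere(nbrs)
        if refine:
            c, r = _gauss_newton_step(nbrs, c, r)
    except np.linalg.LinAlgError:
        return SphereFit(nbrs.mean(axis=0), radius_cap, np.nan, n, clamped=True)
    clamped = False
    if not np.isfinite(r) or r > radius_cap:
        r = radius_cap
        clamped = True
    res = np.linalg.norm(nbrs - c, axis=1) - r
    rms = float(np.sqrt(np.mean(res**2)))
    return SphereFit(c, float(r), rms, n, clamped=clamped)


def compute_curvature(
    pc: SurfacePointCloud,
    neighborhood_radius: float = 3.0,
    neighbor_source: Optional[np.ndarray] = None,
    min_neighbors: int = 10,
    radius_cap: float = 1000.0,
    refine: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned curvature C = 1/R_fit per point, with a flag array.

    ``neighbor_source`` lets the 3 mm neighbourhoods be drawn from a larger
    cloud (e.g. the full eyeball surface) than the points being evaluated, so
    fits at the posterior-region rim are not truncated.  Flagged points
    (too few neighbours → NaN; near-planar clamp → 1/radius_cap) are excluded
    from downstream statistics, never imputed.
    """
    query = pc.points
    source = query if neighbor_source is None else np.asarray(neighbor_source, dtype=float)
    tree = cKDTree(source)
    neighborhoods = tree.query_ball_point(query, neighborhood_radius)
    C = np.full(len(query), np.nan)
    flagged = np.zeros(len(query), dtype=bool)
    for i, idx in enumerate(neighborhoods):
        nbrs = source[idx]
        if nbrs.shape[0] < min_neighbors:
            flagged[i] = True
            continue
        try:
            c, r = _algebraic_sphere(nbrs)
            if refine:
                c, r = _gauss_newton_step(nbrs, c, r)
        except np.linalg.LinAlgError:
            C[i] = 1.0 / radius_cap
            flagged[i] = True
            continue
        if not np.isfinite(r) or r > radius_cap:
            C[i] = 1.0 / radius_cap
            flagged[i] = True
        else:
            C[i] = 1.0 / r
    return C, flagged


@dataclass
class TopographyResult:
    """Posterior-region points with per-point D, C and C·D.

    ``flagged`` marks points whose curvature fit was unreliable; they are
    excluded from all shape-parameter statistics.
    """

    points: np.ndarray
    D: np.ndarray
    C: np.ndarray
    CD: np.ndarray
    flagged: np.ndarray
    span_deg: float = 120.0
    neighborhood_mm: float = 3.0
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def bulging_mask(self) -> np.ndarray:
        """Boolean per-point flag for D > 12 mm (elongation/bulging)."""
        return self.D > 12.0

    def polar_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(polar angle from the +Y posterior pole, azimuth) in degrees."""
        pts = self.points
        norms = np.where(self.D == 0, 1.0, self.D)
        polar = np.degrees(np.arccos(np.clip(pts[:, 1] / norms, -1.0, 1.0)))
        azimuth = np.degrees(np.arctan2(pts[:, 2], pts[:, 0]))
        return polar, azimuth

    def to_dataframe(self) -> pd.DataFrame:
        polar, azim = self.polar_coordinates()
        return pd.DataFrame(
            {
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "polar_deg": polar,
                "azimuth_deg": azim,
                "D_mm": self.D,
                "C_per_mm": self.C,
                "CD": self.CD,
                "flagged": self.flagged.astype(int),
            }
        )

    def save_csv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")
        return path

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, span_deg: float = 120.0, neighborhood_mm: float = 3.0):
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        return cls(
            points=pts,
            D=df["D_mm"].to_numpy(dtype=float),
            C=df["C_per_mm"].to_numpy(dtype=float),
            CD=df["CD"].to_numpy(dtype=float),
            flagged=df["flagged"].to_numpy(dtype=bool),
            span_deg=span_deg,
            neighborhood_mm=neighborhood_mm,
        )


def compute_topography(
    pc_eye: SurfacePointCloud,
    span_deg: float = 120.0,
    neighborhood_mm: float = 3.0,
    min_points: int = 200,
    min_neighbors: int = 10,
    radius_cap: float = 1000.0,
    refine: bool = True,
    neighbor_scope: str = "full",
) -> TopographyResult:
    """Full topography of a point cloud already in eye coordinates.

    ``neighbor_scope`` — "full" (default) draws curvature neighbourhoods
    from the entire cloud so rim fits are not truncated; "region" restricts
    them to the posterior region itself.
    """
    region = select_posterior_region(pc_eye, span_deg, min_points)
    D = compute_distance(region.points)
    source = pc_eye.points if neighbor_scope == "full" else None
    C, flagged = compute_curvature(
        region,
        neighborhood_radius=neighborhood_mm,
        neighbor_source=source,
        min_neighbors=min_neighbors,
        radius_cap=radius_cap,
        refine=refine,
    )
    CD = C * D
    meta = dict(region.meta)
    meta["neighbor_scope"] = neighbor_scope
    return TopographyResult(
        points=region.points,
        D=D,
        C=C,
        CD=CD,
        flagged=flagged,
        span_deg=span_deg,
        neighborhood_mm=neighborhood_mm,
        meta=meta,
    )


@dataclass
class TopographyGrid:
    """Azimuthal-equidistant binned maps (polar angle × azimuth).

    Cells without supporting points hold NaN (missing), never zero.
    """

    polar_centers_deg: np.ndarray
    azimuth_centers_deg: np.ndarray
    D: np.ndarray
    C: np.ndarray
    CD: np.ndarray
    count: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        P, A = np.meshgrid(self.polar_centers_deg, self.azimuth_centers_deg, indexing="ij")
        return pd.DataFrame(
            {
                "polar_deg": P.ravel(),
                "azimuth_deg": A.ravel(),
                "D_mm": self.D.ravel(),
                "C_per_mm": self.C.ravel(),
                "CD": self.CD.ravel(),
                "n": self.count.ravel().astype(int),
            }
        )

    def save_csv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")
        return path


def build_topography_map(result: TopographyResult, grid_res_deg: float = 1.0) -> TopographyGrid:
    """Bin per-point values onto a (polar, azimuth) grid by cell mean.

    D uses every point; C and C·D use unflagged points only.
    """
    if grid_res_deg <= 0:
        raise ValueError("grid_res_deg must be > 0")
    polar, azim = result.polar_coordinates()
    half_span = result.span_deg / 2.0
    n_p = max(1, int(np.ceil(half_span / grid_res_deg)))
    n_a = max(1, int(np.ceil(360.0 / grid_res_deg)))
    ip = np.clip((polar / grid_res_deg).astype(int), 0, n_p - 1)
    ia = np.clip(((azim + 180.0) / grid_res_deg).astype(int), 0, n_a - 1)

    def cell_mean(values, mask):
        s = np.zeros((n_p, n_a))
        c = np.zeros((n_p, n_a))
        np.add.at(s, (ip[mask], ia[mask]), values[mask])
        np.add.at(c, (ip[mask], ia[mask]), 1.0)
        with np.errstate(invalid="ignore"):
            out = np.where(c > 0, s / np.where(c > 0, c, 1.0), np.nan)
        return out, c

    all_mask = np.ones(result.n_points, dtype=bool)
    good = ~result.flagged & np.isfinite(result.C)
    grid_D, count = cell_mean(result.D, all_mask)
    grid_C, _ = cell_mean(np.nan_to_num(result.C), good)
    grid_CD, _ = cell_mean(np.nan_to_num(result.CD), good)
    centers_p = (np.arange(n_p) + 0.5) * grid_res_deg
    centers_a = (np.arange(n_a) + 0.5) * grid_res_deg - 180.0
    return TopographyGrid(centers_p, centers_a, grid_D, grid_C, grid_CD, count)


def render_topography_map(grid: TopographyGrid, path, title: str = "") -> Path:
    """Render D and C maps as two polar panels (PNG), posterior pole at center."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def edges(centers):
        res = centers[1] - centers[0] if len(centers) > 1 else 2 * abs(centers[0])
        return np.append(centers - res / 2.0, centers[-1] + res / 2.0)

    theta = np.deg2rad(edges(grid.azimuth_centers_deg))
    r = edges(grid.polar_centers_deg)
    fig, axes = plt.subplots(1, 2, subplot_kw={"projection": "polar"}, figsize=(11, 5))
    for ax, data, label in ((axes[0], grid.D, "D (mm)"), (axes[1], grid.C, "C (mm$^{-1}$)")):
        mesh = ax.pcolormesh(theta, r, data, shading="auto", cmap="turbo")
        ax.set_title(label)
        ax.set_yticks([15, 30, 45, 60])
        fig.colorbar(mesh, ax=ax, shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
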