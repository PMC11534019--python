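"""Volume and surface I/O.

All world coordinates in this package are millimetres, obtained by mapping
voxel indices through the header affine.  Downstream geometry never sees the
voxel grid again, which makes every computation independent of acquisition
orientation and (after resampling) of anisotropic slice spacing.

Volumes are binary eyeball masks (e.g. from an automated segmentation of
T2-weighted orbital MRI).  Typical acquisitions have ~0.5 mm in-plane pixels
and 1 mm slices; :func:`resample_isotropic` brings them to a uniform 0.5 mm
grid before any surface work.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .errors import (
    EmptyForegroundError,
    SurfaceExtractionError,
    UnsupportedFormatError,
    VolumeReadError,
)

__all__ = [
    "LabeledVolume",
    "SurfacePointCloud",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "extract_surface",
    "read_surface",
    "write_surface",
]


@dataclass
class LabeledVolume:
    """Binary eyeball mask with voxel spacing and voxel-to-world affine (mm).

    ``voxels`` is indexed (i, j, k); ``affine`` maps homogeneous voxel indices
    to world mm.  ``axis_labels`` tags the anatomical direction of each voxel
    axis (nibabel convention, e.g. ('R', 'A', 'S')).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    axis_labels: tuple = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], atol=1e-6))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if out.shape[0] == 1 else out


@dataclass
class SurfacePointCloud:
    """Points (N x 3, world mm) sampled on the eyeball surface.

    ``normals`` are optional outward unit vectors; ``meta`` carries provenance
    (smoothing sigma, source id, laterality/chirality flags).
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("surface points must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length within 1e-6")

    def __len__(self) -> int:
        return self.points.shape[0]

    def replace(self, **kwargs) -> "SurfacePointCloud":
        return dataclasses.replace(self, **kwargs)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask.astype(np.uint8)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == int(np.argmax(counts))).astype(np.uint8)


def _read_nifti(path: Path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = np.asarray(img.affine, dtype=float)
    return data, affine


def _read_nrrd(path: Path):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (x, y, z) indexing
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = direction @ np.diag(spacing)
    affine[:3, 3] = origin
    return data, affine


def read_volume(path, label: Optional[int] = None) -> LabeledVolume:
    """Read a NIfTI or NRRD mask and return a single-component binary volume.

    Parameters
    ----------
    path
        ``.nii`` / ``.nii.gz`` or ``.nrrd`` / ``.nhdr`` file.
    label
        If the file is multi-label, keep only voxels equal to this label id;
        otherwise any nonzero voxel is foreground.

    The largest connected foreground component is kept — segmentation output
    is assumed to contain a single clean eyeball, possibly with small spurious
    islands.
    """
    path = Path(path)
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            data, affine = _read_nifti(path)
        elif name.endswith((".nrrd", ".nhdr")):
            data, affine = _read_nrrd(path)
        else:
            raise VolumeReadError(f"unrecognized volume format: {path.name}")
    except VolumeReadError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any reader failure
        raise VolumeReadError(f"could not read volume {path}: {exc}") from exc

    data = np.asarray(data)
    if data.ndim != 3:
        raise VolumeReadError(f"expected a 3D volume, got shape {data.shape}")
    mask = (data == label) if label is not None else (data > 0.5)
    if not mask.any():
        raise EmptyForegroundError(
            f"empty foreground in {path}"
            + (f" for label {label}" if label is not None else "")
        )
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeReadError(f"non-invertible affine in {path}")
    mask = _largest_component(mask)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    try:
        labels = nib.orientations.aff2axcodes(affine)
    except Exception:  # noqa: BLE001
        labels = ("R", "A", "S")
    return LabeledVolume(mask, spacing, affine, tuple(labels))


def write_volume(vol: LabeledVolume, path) -> Path:
    """Write a mask as NIfTI (by suffix); returns the path."""
    path = Path(path)
    if not path.name.lower().endswith((".nii", ".nii.gz")):
        raise UnsupportedFormatError(f"volume writing supports NIfTI only, got {path.name}")
    img = nib.Nifti1Image(vol.voxels.astype(np.uint8), vol.affine)
    nib.save(img, str(path))
    return path


def resample_isotropic(
    vol: LabeledVolume, target_spacing: float = 0.5, order: int = 1, threshold: float = 0.5
) -> LabeledVolume:
    """Resample the mask to isotropic ``target_spacing`` mm.

    The mask is interpolated as a scalar field (default linear, ``order``
    configurable) and re-thresholded at ``threshold``, which preserves the
    sub-voxel boundary position far better than nearest-neighbour for smooth
    convex shapes.  Already-isotropic input at the target spacing is returned
    unchanged.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    if np.allclose(vol.spacing, target_spacing, atol=1e-9):
        return vol
    scale = target_spacing / vol.spacing  # input voxels per output voxel
    out_shape = np.maximum(
        1, np.ceil(np.asarray(vol.voxels.shape) / scale).astype(int)
    )
    # cell-aligned sampling: output cell edges coincide with input cell edges,
    # so output samples never land exactly on the 0.5-level midpoints between
    # input voxel centers (which would bias the thresholded boundary by half
    # an output voxel)
    offset = (scale - 1.0) / 2.0
    resampled = ndimage.affine_transform(
        vol.voxels.astype(np.float32),
        np.diag(scale),
        offset=offset,
        output_shape=tuple(out_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    mask = (resampled >= threshold).astype(np.uint8)
    new_affine = vol.affine @ np.diag([scale[0], scale[1], scale[2], 1.0])
    new_affine[:3, 3] += vol.affine[:3, :3] @ offset
    return LabeledVolume(mask, np.full(3, float(target_spacing)), new_affine, vol.axis_labels)


def extract_surface(vol: LabeledVolume, sigma: float = 1.0, iso_level: float = 0.5) -> SurfacePointCloud:
    """Gaussian-smooth the mask and extract a surface point cloud.

    The binary mask is smoothed with an isotropic Gaussian of ``sigma`` mm
    (``sigma=0`` skips smoothing), marching cubes is run at ``iso_level`` and
    the vertices are mapped through the affine to world mm.  The default
    sigma of 1 mm (two voxels at the standard 0.5 mm grid) suppresses the
    grid-lattice ripple that a one-voxel smooth leaves in the surface
    (~0.035 mm RMS radially on a voxelized sphere), which otherwise inflates
    the noise-sensitive 95th-percentile curvature statistics; the induced
    shrinkage is ~0.15 mm on a 12 mm globe.  Vertex normals
    (from the smoothed field gradient) are oriented outward.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not vol.is_isotropic:
        raise ValueError("volume must be isotropic; call resample_isotropic first")
    if vol.foreground_count == 0:
        raise EmptyForegroundError("empty mask")
    field_ = vol.voxels.astype(np.float32)
    if sigma > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=sigma / vol.spacing[0])
    # pad so surfaces close even when foreground touches the grid border
    field_ = np.pad(field_, 1, mode="constant", constant_values=0.0)
    if field_.max() <= iso_level:
        raise SurfaceExtractionError("mask too small: smoothed field never reaches iso-level")
    try:
        verts, _faces, normals, _vals = measure.marching_cubes(field_, level=iso_level)
    except (ValueError, RuntimeError) as exc:
        raise SurfaceExtractionError(f"marching cubes produced no surface: {exc}") from exc
    verts = verts - 1.0  # undo padding offset
    world = verts @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    rot = vol.affine[:3, :3] / vol.spacing[np.newaxis, :]
    n_world = normals @ rot.T
    lens = np.linalg.norm(n_world, axis=1)
    lens[lens == 0] = 1.0
    n_world = n_world / lens[:, None]
    # orient outward: the field decreases outward, so check against centroid
    centroid = world.mean(axis=0)
    if np.mean(np.einsum("ij,ij->i", world - centroid, n_world)) < 0:
        n_world = -n_world
    return SurfacePointCloud(
        world,
        n_world,
        meta={"sigma_mm": float(sigma), "source": "marching_cubes", "iso_level": float(iso_level)},
    )


_CSV_HEADER = "x_mm,y_mm,z_mm"


def write_surface(pc: SurfacePointCloud, path, format: Optional[str] = None) -> Path:
    """Write a point cloud as PLY, OBJ or CSV (coordinates kept to 6 decimals)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    pts = pc.points
    if fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(pts)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            if pc.normals is not None:
                fh.write("property double nx\nproperty double ny\nproperty double nz\n")
            fh.write("end_header\n")
            if pc.normals is not None:
                for p, n in zip(pts, pc.normals):
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {n[0]:.6f} {n[1]:.6f} {n[2]:.6f}\n")
            else:
                for p in pts:
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    elif fmt == "obj":
        with open(path, "w") as fh:
            for p in pts:
                fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    elif fmt == "csv":
        header = _CSV_HEADER
        data = pts
        if pc.normals is not None:
            header += ",nx,ny,nz"
            data = np.hstack([pts, pc.normals])
        np.savetxt(path, data, fmt="%.6f", delimiter=",", header=header, comments="")
    else:
        raise UnsupportedFormatError(f"unsupported surface format: {fmt!r} (use PLY, OBJ or CSV)")
    return path


def read_surface(path) -> SurfacePointCloud:
    """Read a point cloud from PLY, OBJ or CSV."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "ply":
        loaded = trimesh.load(str(path), process=False)
        pts = np.asarray(loaded.vertices, dtype=float)
        normals = None
        raw = getattr(loaded, "metadata", {}).get("_ply_raw", {})
        vert = raw.get("vertex", {}).get("data") if raw else None
        if vert is not None:
            try:
                names = vert.dtype.names if hasattr(vert, "dtype") else vert.keys()
                if {"nx", "ny", "nz"} <= set(names):
                    normals = np.column_stack(
                        [np.asarray(vert["nx"]), np.asarray(vert["ny"]), np.asarray(vert["nz"])]
                    ).astype(float).reshape(-1, 3)
            except (KeyError, TypeError):
                normals = None
        if normals is not None:
            lens = np.linalg.norm(normals, axis=1)
            normals = normals / np.where(lens == 0, 1.0, lens)[:, None]
        return SurfacePointCloud(pts, normals, meta={"source": str(path)})
    if fmt == "obj":
        pts = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("v "):
                    pts.append([float(v) for v in line.split()[1:4]])
        if not pts:
            raise UnsupportedFormatError(f"no vertices found in {path}")
        return SurfacePointCloud(np.asarray(pts), meta={"source": str(path)})
    if fmt == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        normals = None
        if {"nx", "ny", "nz"}.issubset(df.columns):
            normals = df[["nx", "ny", "nz"]].to_numpy(dtype=float)
            lens = np.linalg.norm(normals, axis=1)
            normals = normals / np.where(lens == 0, 1.0, lens)[:, None]
        return SurfacePointCloud(pts, normals, meta={"source": str(path)})
    raise UnsupportedFormatError(f"unsupported surface format: {fmt!r} (use PLY, OBJ or CSV)")
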