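"""End-to-end pipeline: mask (or surface) → frame → topography → parameters.

Two entry points cover the two input kinds:

* :func:`analyze_volume` — binary mask volume: resample to isotropic 0.5 mm,
  smooth + marching cubes, inscribed-sphere frame, topography, parameters.
* :func:`analyze_surface` — surface point cloud (e.g. analytic phantom or an
  externally extracted mesh): same, with the inscribed sphere found by
  continuous search against the point k-d tree.

:func:`run_pipeline` wraps :func:`analyze_volume` with file I/O, artifact
writing (frame.json, topo.csv, grid.csv, topo.png, params.json) and
per-stage logging; it backs the ``sclera-topo run`` command.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import __version__
from .axis import (
    EyeFrame,
    build_eye_frame,
    chebyshev_center,
    find_corneal_vertex,
    find_inscribed_sphere,
    to_eye_coordinates,
)
from .io import LabeledVolume, SurfacePointCloud, extract_surface, read_volume, resample_isotropic
from .params import ShapeParameters, compute_parameters
from .topography import (
    TopographyResult,
    build_topography_map,
    compute_topography,
    render_topography_map,
)

log = logging.getLogger("scleratopo")

__all__ = ["RunConfig", "PipelineResult", "analyze_volume", "analyze_surface", "run_pipeline"]

_HINTS = {
    "+x": (1, 0, 0),
    "-x": (-1, 0, 0),
    "+y": (0, 1, 0),
    "-y": (0, -1, 0),
    "+z": (0, 0, 1),
    "-z": (0, 0, -1),
}


def resolve_hint(hint: Union[str, Sequence[float]]) -> np.ndarray:
    """Map 'auto'/'+y'/... or an explicit vector to a unit anterior direction.

    'auto' assumes RAS-style world coordinates where anterior is +Y — the
    nibabel convention for NIfTI affines.  Pass an explicit direction when
    the header orientation is unreliable.
    """
    if isinstance(hint, str):
        key = hint.lower()
        if key == "auto":
            return np.array([0.0, 1.0, 0.0])
        if key in _HINTS:
            return np.asarray(_HINTS[key], dtype=float)
        raise ValueError(f"unknown anterior hint {hint!r}")
    v = np.asarray(hint, dtype=float).reshape(3)
    return v / np.linalg.norm(v)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the method's standard constants
    (12 mm origin offset, 120° span, 3 mm curvature neighbourhood, 95th
    percentile, 0.5 mm grid, 1 mm surface smoothing)."""

    input: str = ""
    laterality: str = "OD"
    anterior_hint: Union[str, Sequence[float]] = "auto"
    offset_mm: float = 12.0
    span_deg: float = 120.0
    neighborhood_mm: float = 3.0
    smoothing_sigma_mm: float = 1.0
    percentile: float = 95.0
    grid_res_deg: float = 1.0
    target_spacing_mm: float = 0.5
    label: Optional[int] = None
    mirror_left: bool = True
    seed: int = 0
    outdir: str = "scleratopo_out"

    def __post_init__(self):
        for name in (
            "offset_mm",
            "span_deg",
            "neighborhood_mm",
            "percentile",
            "grid_res_deg",
            "target_spacing_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smoothing_sigma_mm < 0:
            raise ValueError("smoothing_sigma_mm must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a config file; explicit keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not isinstance(d["anterior_hint"], str):
            d["anterior_hint"] = list(map(float, d["anterior_hint"]))
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    frame: EyeFrame
    surface_eye: SurfacePointCloud
    topography: TopographyResult
    parameters: ShapeParameters
    timings: dict = field(default_factory=dict)


def _finish(
    pc_world: SurfacePointCloud,
    center: np.ndarray,
    radius: float,
    hint: np.ndarray,
    cfg: RunConfig,
    timings: dict,
) -> PipelineResult:
    t0 = time.perf_counter()
    vertex = find_corneal_vertex(pc_world, center, hint)
    frame = build_eye_frame(
        center,
        vertex,
        offset=cfg.offset_mm,
        laterality=cfg.laterality,
        sphere_radius=radius,
    )
    pc_eye = to_eye_coordinates(pc_world, frame, mirror_left=cfg.mirror_left)
    timings["frame"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    topo = compute_topography(
        pc_eye, span_deg=cfg.span_deg, neighborhood_mm=cfg.neighborhood_mm
    )
    timings["topography"] = time.perf_counter() - t0
    params_ = compute_parameters(topo, percentile=cfg.percentile)
    log.info(
        "topography: %d posterior points, %d flagged", topo.n_points, topo.n_flagged
    )
    return PipelineResult(frame, pc_eye, topo, params_, timings)


def analyze_volume(vol: LabeledVolume, config: Optional[RunConfig] = None, **kwargs) -> PipelineResult:
    """Run the full method on a binary mask volume."""
    cfg = config or RunConfig(**kwargs)
    timings: dict = {}
    t0 = time.perf_counter()
    if not vol.is_isotropic or not np.allclose(vol.spacing, cfg.target_spacing_mm):
        vol = resample_isotropic(vol, cfg.target_spacing_mm)
    pc = extract_surface(vol, sigma=cfg.smoothing_sigma_mm)
    timings["surface"] = time.perf_counter() - t0
    log.info("surface: %d points at %.2f mm spacing", len(pc), cfg.target_spacing_mm)
    t0 = time.perf_counter()
    center, radius = find_inscribed_sphere(vol)
    timings["inscribed_sphere"] = time.perf_counter() - t0
    hint = resolve_hint(cfg.anterior_hint)
    return _finish(pc, center, radius, hint, cfg, timings)


def analyze_surface(pc: SurfacePointCloud, config: Optional[RunConfig] = None, **kwargs) -> PipelineResult:
    """Run the method on a surface point cloud (world mm)."""
    cfg = config or RunConfig(**kwargs)
    timings: dict = {}
    t0 = time.perf_counter()
    center, radius = chebyshev_center(pc.points)
    timings["inscribed_sphere"] = time.perf_counter() - t0
    hint = resolve_hint(cfg.anterior_hint)
    return _finish(pc, center, radius, hint, cfg, timings)


def run_pipeline(config: RunConfig) -> dict:
    """File-to-artifacts pipeline; returns a manifest of written paths.

    Deterministic given identical inputs and config; every artifact directory
    carries a run.json with the package version and a config hash.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "io"
    try:
        vol = read_volume(config.input, label=config.label)
        stage = "analysis"
        result = analyze_volume(vol, config)
        stage = "artifacts"
        frame_path = result.frame.save(outdir / "frame.json")
        topo_path = result.topography.save_csv(outdir / "topo.csv")
        grid = build_topography_map(result.topography, config.grid_res_deg)
        grid_path = grid.save_csv(outdir / "grid.csv")
        png_path = render_topography_map(grid, outdir / "topo.png", title=Path(config.input).name)
        params_path = outdir / "params.json"
        params_path.write_text(json.dumps(result.parameters.to_dict(units=True), indent=2))
        run_path = outdir / "run.json"
        run_path.write_text(
            json.dumps(
                {
                    "version": __version__,
                    "config": config.to_dict(),
                    "config_hash": config.digest(),
                    "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
                },
                indent=2,
            )
        )
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    return {
        "frame": frame_path,
        "topo": topo_path,
        "grid": grid_path,
        "png": png_path,
        "params": params_path,
        "run": run_path,
    }
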