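"""Scalar shape parameters of the posterior sclera.

Seven descriptors summarize the topography over the 120° posterior region:

===========  =============  =====================================================
parameter    units          meaning
===========  =============  =====================================================
D_mean       mm             mean deviation from the pre-elongation eye center
C_mean       mm⁻¹           mean posterior curvature
D_max        mm             95th percentile of D (robust maximum offset)
C_max        mm⁻¹           95th percentile of C (robust sharpest bend)
D_var        mm²            variance of D; 0 for a centered sphere, grows with
                            any deviation from sphericity
CD_mean      dimensionless  mean of the per-point product C·D
CD_max       dimensionless  95th percentile of per-point C·D; ≈1 for a normal
                            24 mm eye, amplified by elongation plus sharp bulge
===========  =============  =====================================================

The 95th percentile stands in for the maximum to resist outlier surface
points.  Percentiles use linear interpolation between order statistics and
the variance uses the population (1/N) denominator — both conventions are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientPointsError
from .topography import TopographyResult

__all__ = ["ShapeParameters", "compute_parameters", "parameters_table", "PARAMETER_UNITS"]

PARAMETER_UNITS = {
    "D_mean": "mm",
    "C_mean": "1/mm",
    "D_max": "mm",
    "C_max": "1/mm",
    "D_var": "mm^2",
    "CD_mean": "",
    "CD_max": "",
}

PARAMETER_NAMES = tuple(PARAMETER_UNITS)


@dataclass(frozen=True)
class ShapeParameters:
    D_mean: float
    C_mean: float
    D_max: float
    C_max: float
    D_var: float
    CD_mean: float
    CD_max: float
    n_points: int
    n_flagged: int

    def to_dict(self, units: bool = False) -> dict:
        d = {name: float(getattr(self, name)) for name in PARAMETER_NAMES}
        d["n_points"] = self.n_points
        d["n_flagged"] = self.n_flagged
        if units:
            d["units"] = dict(PARAMETER_UNITS)
        return d

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())


def compute_parameters(
    result: TopographyResult,
    percentile: float = 95.0,
    ddof: int = 0,
    min_points: int = 200,
) -> ShapeParameters:
    """Compute the seven shape parameters from a topography result.

    Flagged points (unreliable curvature fits) are excluded from every
    statistic.  D statistics could in principle use all points, but using one
    consistent point set keeps D-, C- and C·D-statistics comparable.
    """
    good = ~result.flagged & np.isfinite(result.C)
    n_good = int(good.sum())
    if n_good < min_points:
        raise InsufficientPointsError(
            f"only {n_good} unflagged posterior points (need {min_points})"
        )
    D = result.D[good]
    C = result.C[good]
    CD = result.CD[good]
    return ShapeParameters(
        D_mean=float(np.mean(D)),
        C_mean=float(np.mean(C)),
        D_max=float(np.percentile(D, percentile)),
        C_max=float(np.percentile(C, percentile)),
        D_var=float(np.var(D, ddof=ddof)),
        CD_mean=float(np.mean(CD)),
        CD_max=float(np.percentile(CD, percentile)),
        n_points=result.n_points,
        n_flagged=result.n_flagged,
    )


def parameters_table(
    batch: Sequence[ShapeParameters],
    labels: Sequence[str],
    groups: Optional[Sequence] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format parameter table plus a per-group mean ± SD summary.

    Returns ``(long, summary)``.  ``long`` has columns
    (eye_id, group, parameter, value); ``summary`` has one row per
    (group, parameter) with n, mean and SD (SD is missing, not zero, for a
    single eye).
    """
    if len(batch) != len(labels):
        raise ValueError(f"{len(batch)} parameter sets but {len(labels)} labels")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate eye ids in labels")
    if groups is None:
        groups = ["all"] * len(batch)
    if len(groups) != len(batch):
        raise ValueError(f"{len(batch)} parameter sets but {len(groups)} group labels")
    rows = []
    for sp, eye_id, group in zip(batch, labels, groups):
        for name in PARAMETER_NAMES:
            rows.append(
                {"eye_id": eye_id, "group": group, "parameter": name, "value": float(getattr(sp, name))}
            )
    long = pd.DataFrame(rows)
    summary = (
        long.groupby(["group", "parameter"], sort=False)["value"]
        .agg(n="count", mean="mean", sd="std")  # std has ddof=1 → NaN for n=1
        .reset_index()
    )
    return long, summary


def save_parameters_csv(long: pd.DataFrame, path) -> Path:
    path = Path(path)
    long.to_csv(path, index=False, float_format="%.6f")
    return path
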