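"""ROC discrimination statistics: AUC and high-specificity partial AUC.

The full AUC is computed through the Mann–Whitney rank identity (ties count
½), i.e. the probability that a randomly drawn positive scores above a
randomly drawn negative.  The partial AUC integrates the empirical ROC curve
over the high-specificity band only (specificity 85–100%, i.e. false
positive rate 0–0.15) by the trapezoid rule on the curve's vertices, and is
normalized by the band width 0.15 so a perfect classifier scores 1.0 and
the chance diagonal scores 0.15/2 = 0.075.

Because the shape parameters are directionless descriptors, orientation is
chosen automatically so AUC ≥ 0.5, and the chosen direction is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = ["ROCResult", "auc", "partial_auc", "pairwise_report"]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    partial_auc_normalized: float
    spec_range: tuple = (0.85, 1.0)
    n_pos: int = 0
    n_neg: int = 0
    orientation: str = "positive-high"


def _prepare(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    pos = labels == classes[1]
    return scores, pos


def _mann_whitney_auc(scores: np.ndarray, pos: np.ndarray) -> float:
    ranks = rankdata(scores)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _partial_auc_fpr(scores: np.ndarray, pos: np.ndarray, fpr_max: float) -> float:
    """Raw area under the empirical ROC over FPR ∈ [0, fpr_max] (trapezoid)."""
    fpr, tpr, _ = roc_curve(pos.astype(int), scores, drop_intermediate=False)
    # clip the polyline at fpr_max
    tpr_at = np.interp(fpr_max, fpr, tpr)
    keep = fpr <= fpr_max
    f = np.append(fpr[keep], fpr_max)
    t = np.append(tpr[keep], tpr_at)
    return float(np.trapezoid(t, f))


def auc(scores: Sequence[float], labels: Sequence, spec_lo: float = 0.85, orient: str = "auto") -> ROCResult:
    """Full AUC (Mann–Whitney, ties ½) with the normalized partial AUC.

    With ``orient="auto"`` (default) the direction is chosen so the reported
    AUC ≥ 0.5 — shape parameters are directionless discriminators — and
    ``orientation`` records which class scored higher.  ``orient="none"``
    keeps the positive-high convention; use it when the chance level itself
    is of interest (direction selection biases chance-level partial AUC
    upward, since it takes the better of two noisy directions).
    """
    scores, pos = _prepare(scores, labels)
    a = _mann_whitney_auc(scores, pos)
    flip = orient == "auto" and a < 0.5
    oriented = -scores if flip else scores
    orientation = "positive-low" if flip else "positive-high"
    a_or = 1.0 - a if flip else a
    fpr_max = 1.0 - spec_lo
    pauc = _partial_auc_fpr(oriented, pos, fpr_max) / fpr_max
    return ROCResult(
        auc=a_or,
        partial_auc_normalized=pauc,
        spec_range=(spec_lo, 1.0),
        n_pos=int(pos.sum()),
        n_neg=int((~pos).sum()),
        orientation=orientation,
    )


def partial_auc(
    scores: Sequence[float], labels: Sequence, spec_lo: float = 0.85, orient: str = "auto"
) -> ROCResult:
    """Normalized partial AUC over specificity ∈ [spec_lo, 1] (alias of :func:`auc`)."""
    return auc(scores, labels, spec_lo=spec_lo, orient=orient)


def brute_force_auc(scores: Sequence[float], labels: Sequence) -> float:
    """O(n²) pair-counting AUC — the independent oracle used in tests."""
    scores, pos = _prepare(scores, labels)
    sp = scores[pos]
    sn = scores[~pos]
    gt = (sp[:, None] > sn[None, :]).sum()
    eq = (sp[:, None] == sn[None, :]).sum()
    return float((gt + 0.5 * eq) / (sp.size * sn.size))


def pairwise_report(
    params_long: pd.DataFrame,
    group_column: str = "group",
    value_column: str = "value",
    parameter_column: str = "parameter",
    spec_lo: float = 0.85,
) -> pd.DataFrame:
    """AUC / partial AUC for every parameter and every group pair.

    ``params_long`` is the long-format table from
    :func:`scleratopo.params.parameters_table` (columns eye_id, group,
    parameter, value).  Rows with missing values are excluded pairwise and
    the per-group n is reported; groups with fewer than 2 members are
    flagged in the ``note`` column.
    """
    groups = [g for g in params_long[group_column].unique()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for param, sub in params_long.groupby(parameter_column, sort=False):
        for ga, gb in combinations(groups, 2):
            va = sub.loc[sub[group_column] == ga, value_column].dropna().to_numpy()
            vb = sub.loc[sub[group_column] == gb, value_column].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                raise ValueError(f"group {ga if va.size == 0 else gb} is empty for {param}")
            note = "" if (va.size >= 2 and vb.size >= 2) else "group with < 2 members"
            scores = np.concatenate([va, vb])
            labels = np.concatenate([np.zeros(va.size), np.ones(vb.size)])
            res = auc(scores, labels, spec_lo=spec_lo)
            rows.append(
                {
                    "parameter": param,
                    "group_a": ga,
                    "group_b": gb,
                    "auc": res.auc,
                    "partial_auc_normalized": res.partial_auc_normalized,
                    "n_a": int(va.size),
                    "n_b": int(vb.size),
                    "note": note,
                }
            )
    return pd.DataFrame(rows)
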