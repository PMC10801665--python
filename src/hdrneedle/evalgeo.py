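"""Geometric accuracy metrics for needle segmentation and digitization.

Segmentation overlap is scored with the Dice similarity coefficient and
Jaccard index, worst-case boundary mismatch with the exact (maximum)
Hausdorff distance in physical mm.  Digitization accuracy is scored per
matched needle pair: the tip error is the mean absolute difference of
needle lengths along the fitted curves, and the shaft error is the mean
in-plane distance between the two fitted centerlines evaluated at common
z-slices.  A classic paired t-test compares per-case metric lists between
two methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .grid import Volume
from .digitize import Trajectory


@dataclass
class GeoReport:
    """Per-case geometric evaluation summary (fractions and mm)."""

    dsc: float
    jaccard: float
    hausdorff_mm: float
    tip_error_mm: float
    shaft_error_mm: float
    n_needles: int
    tip_distance_mm: float = float("nan")  # secondary: Euclidean tip-to-tip
    per_needle: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dsc_pct": 100.0 * self.dsc,
            "jaccard_pct": 100.0 * self.jaccard,
            "hausdorff_mm": self.hausdorff_mm,
            "tip_error_mm": self.tip_error_mm,
            "shaft_error_mm": self.shaft_error_mm,
            "tip_distance_mm": self.tip_distance_mm,
            "n_needles": self.n_needles,
            "per_needle": self.per_needle,
        }


def _as_bool(mask: Volume | np.ndarray) -> np.ndarray:
    data = mask.data if isinstance(mask, Volume) else mask
    return np.asarray(data) > 0


def _check_grids(p: Volume | np.ndarray, t: Volume | np.ndarray) -> None:
    if isinstance(p, Volume) and isinstance(t, Volume):
        p.require_same_grid(t)
    else:
        pa, ta = _as_bool(p), _as_bool(t)
        if pa.shape != ta.shape:
            raise ValueError(f"grid mismatch: {pa.shape} vs {ta.shape}")


def dsc(pred: Volume | np.ndarray, truth: Volume | np.ndarray) -> float:
    """Dice similarity coefficient 2|P∩T| / (|P|+|T|); 1.0 when both empty."""
    _check_grids(pred, truth)
    p, t = _as_bool(pred), _as_bool(truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        warnings.warn("DSC of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def jaccard(pred: Volume | np.ndarray, truth: Volume | np.ndarray) -> float:
    """Jaccard index |P∩T| / |P∪T|; 1.0 when both empty."""
    _check_grids(pred, truth)
    p, t = _as_bool(pred), _as_bool(truth)
    union = int((p | t).sum())
    if union == 0:
        warnings.warn("Jaccard of two empty masks defined as 1.0")
        return 1.0
    return int((p & t).sum()) / union


def hausdorff(a: Volume | np.ndarray, b: Volume | np.ndarray,
              spacing: tuple[float, float, float] | None = None) -> float:
    """Exact symmetric Hausdorff distance between two masks, in mm.

    Voxel centers are scaled by the physical spacing, so the distance is
    anisotropy-aware.  The exact maximum is reported (not a percentile).
    Empty masks are an error: the Hausdorff distance is undefined.
    """
    if spacing is None:
        if isinstance(a, Volume):
            spacing = a.spacing
        else:
            raise ValueError("spacing required when masks are plain arrays")
    _check_grids(a, b)
    pa, pb = _as_bool(a), _as_bool(b)
    if not pa.any() or not pb.any():
        raise ValueError("Hausdorff distance is undefined for empty masks")
    sp = np.asarray(spacing, dtype=float)
    ca = np.argwhere(pa) * sp
    cb = np.argwhere(pb) * sp
    d_ab = cKDTree(cb).query(ca, k=1)[0].max()
    d_ba = cKDTree(ca).query(cb, k=1)[0].max()
    return float(max(d_ab, d_ba))


def tip_error(pairs: list[tuple[Trajectory, Trajectory]]) -> tuple[float, float]:
    """Mean absolute needle-length difference over matched pairs, in mm.

    Needle length is the arc length of the fitted curve from entry to tip.
    Returns ``(tip_error, tip_distance)``: the secondary value is the mean
    Euclidean distance between tip points, reported as a diagnostic only.
    """
    if not pairs:
        raise ValueError("tip_error needs at least one matched pair")
    dlen = [abs(p.length_mm - t.length_mm) for p, t in pairs]
    dtip = [float(np.linalg.norm(np.subtract(p.tip, t.tip))) for p, t in pairs]
    return float(np.mean(dlen)), float(np.mean(dtip))


def shaft_error(pairs: list[tuple[Trajectory, Trajectory]],
                z_tol: float = 1e-6) -> float:
    """Mean in-plane distance between fitted centerlines at common z-slices.

    For each pair, the z values present in both trajectories' point lists
    (within ``z_tol``) are collected; at each such z the in-plane Euclidean
    distance ||P(x,y) − T(x,y)|| between the two fitted curves is taken.
    The result averages over needles and slices; pairs without common
    slices are excluded with a warning.
    """
    if not pairs:
        raise ValueError("shaft_error needs at least one matched pair")
    per_needle_means = []
    for p, t in pairs:
        zp = p.points[:, 2]
        zt = t.points[:, 2]
        common = zp[np.min(np.abs(zp[:, None] - zt[None, :]), axis=1) <= z_tol]
        if common.size == 0:
            warnings.warn("trajectory pair without common z-slices excluded from shaft error")
            continue
        d = np.linalg.norm(p.xy_at(common) - t.xy_at(common), axis=1)
        per_needle_means.append(d.mean())
    if not per_needle_means:
        raise ValueError("no trajectory pair shares any z-slice")
    return float(np.mean(per_needle_means))


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on per-case metric lists.

    Returns (t statistic, p value) with n-1 degrees of freedom.  Zero
    variance of the differences (e.g. identical lists) is an error: the
    statistic is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t needs two equal-length 1-D samples of size >= 2")
    if np.var(a - b, ddof=1) == 0:
        raise ValueError("paired t-test undefined: differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def evaluate_case(
    pred_mask: Volume,
    truth_mask: Volume,
    pred_traj: list[Trajectory],
    truth_traj: list[Trajectory],
) -> GeoReport:
    """Full geometric report for one case (masks + matched trajectories).

    Needles flagged as merged are excluded from tip/shaft statistics; the
    overlap metrics always use the full masks.
    """
    from .digitize import match_needles

    d = dsc(pred_mask, truth_mask)
    j = jaccard(pred_mask, truth_mask)
    if _as_bool(pred_mask).any() and _as_bool(truth_mask).any():
        h = hausdorff(pred_mask, truth_mask)
    else:
        warnings.warn("empty mask: Hausdorff distance reported as NaN")
        h = float("nan")
    usable_pred = [t for t in pred_traj if not t.merged_flag]
    per_needle: list[dict] = []
    if usable_pred and truth_traj:
        pairs_idx, _, _ = match_needles(usable_pred, truth_traj)
        pairs = [(usable_pred[i], truth_traj[j_]) for i, j_ in pairs_idx]
        te, td = tip_error(pairs)
        se = shaft_error(pairs)
        for (i, j_), (p, t) in zip(pairs_idx, pairs):
            per_needle.append({
                "pred_index": i,
                "truth_index": j_,
                "length_pred_mm": p.length_mm,
                "length_truth_mm": t.length_mm,
                "tip_distance_mm": float(np.linalg.norm(np.subtract(p.tip, t.tip))),
            })
        n = len(pairs)
    else:
        te = td = se = float("nan")
        n = 0
    return GeoReport(dsc=d, jaccard=j, hausdorff_mm=h, tip_error_mm=te,
                     shaft_error_mm=se, n_needles=n, tip_distance_mm=td,
                     per_needle=per_needle)
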