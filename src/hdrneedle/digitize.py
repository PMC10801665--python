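"""Needle digitization: from a binary needle mask to per-needle channels.

A predicted (or ground-truth) needle mask is turned into the geometry a
treatment planning system needs: connected components become needle
instances, per-slice centroids give each instance an ordered central
trajectory, a low-degree polynomial fit smooths voxel quantization away,
and dwell positions are placed along the fitted curve by arc length.

Needles in this anatomy are z-monotone (inserted roughly along the slice
axis), which makes the per-slice-centroid parameterization valid; slices
where touching needles merge into one component are detected by an
implausible in-plane centroid jump and flagged rather than split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .grid import Volume

#: quadrature resolution for arc-length tables (samples per curve)
ARC_SAMPLES = 4096


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A needle centerline: ordered mm points, fitted polynomials, tip.

    ``points`` are (x, y, z) in mm with strictly increasing z; ``poly_x``
    and ``poly_y`` are coefficients of x(z), y(z) in ascending order;
    ``tip`` is the curve point at the insertion-direction end; ``length_mm``
    is the arc length from entry to tip along the fitted curve.
    """

    points: np.ndarray
    poly_x: np.ndarray
    poly_y: np.ndarray
    tip: tuple[float, float, float]
    length_mm: float
    merged_flag: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.poly_x = np.asarray(self.poly_x, dtype=float)
        self.poly_y = np.asarray(self.poly_y, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        dz = np.diff(self.points[:, 2])
        if np.any(dz <= 0):
            raise ValueError("trajectory points must be strictly increasing in z")

    # -- evaluation --------------------------------------------------------
    def xy_at(self, z: np.ndarray) -> np.ndarray:
        """In-plane curve position(s) (x, y) at height(s) z (mm)."""
        z = np.asarray(z, dtype=float)
        x = np.polyval(self.poly_x[::-1], z)
        y = np.polyval(self.poly_y[::-1], z)
        return np.stack([x, y], axis=-1)

    @property
    def z_range(self) -> tuple[float, float]:
        return float(self.points[0, 2]), float(self.points[-1, 2])

    def _z_span_to_tip(self) -> tuple[float, float]:
        z0 = float(self.points[0, 2])
        return (z0, float(self.tip[2])) if self.tip[2] >= z0 else (float(self.tip[2]), z0)

    def arc_table(self, n: int = ARC_SAMPLES) -> tuple[np.ndarray, np.ndarray]:
        """(z grid, cumulative arc length from the entry end) by quadrature."""
        za, zb = self._z_span_to_tip()
        z = np.linspace(za, zb, n)
        dx = np.polyval(np.polyder(np.poly1d(self.poly_x[::-1])), z)
        dy = np.polyval(np.polyder(np.poly1d(self.poly_y[::-1])), z)
        ds = np.sqrt(1.0 + dx ** 2 + dy ** 2)
        s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(z))])
        return z, s

    def to_dict(self) -> dict:
        return {
            "points_mm": self.points.tolist(),
            "poly_x": self.poly_x.tolist(),
            "poly_y": self.poly_y.tolist(),
            "tip_mm": list(map(float, self.tip)),
            "length_mm": float(self.length_mm),
            "merged_flag": bool(self.merged_flag),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        return cls(np.asarray(d["points_mm"]), np.asarray(d["poly_x"]),
                   np.asarray(d["poly_y"]), tuple(d["tip_mm"]),
                   float(d["length_mm"]), bool(d.get("merged_flag", False)))


def trajectory_from_polynomial(
    poly_x: np.ndarray,
    poly_y: np.ndarray,
    z_entry: float,
    z_tip: float,
    z_samples: np.ndarray | None = None,
) -> Trajectory:
    """Build an analytic Trajectory from x(z), y(z) coefficients (ascending).

    Used by the phantom generator for closed-form ground truth.  ``points``
    are sampled at ``z_samples`` (default: 33 uniform samples) within
    [z_entry, z_tip]; tip and arc length are exact properties of the curve.
    """
    if z_samples is None:
        z_samples = np.linspace(z_entry, z_tip, 33)
    z_samples = np.asarray(z_samples, dtype=float)
    z_samples = z_samples[(z_samples >= min(z_entry, z_tip) - 1e-9)
                          & (z_samples <= max(z_entry, z_tip) + 1e-9)]
    px = np.asarray(poly_x, dtype=float)
    py = np.asarray(poly_y, dtype=float)
    x = np.polyval(px[::-1], z_samples)
    y = np.polyval(py[::-1], z_samples)
    pts = np.stack([x, y, z_samples], axis=1)
    tip = (float(np.polyval(px[::-1], z_tip)),
           float(np.polyval(py[::-1], z_tip)), float(z_tip))
    traj = Trajectory(pts, px, py, tip, 0.0)
    _, s = traj.arc_table()
    traj.length_mm = float(s[-1])
    return traj


# ---------------------------------------------------------------------------
# dwell sets
# ---------------------------------------------------------------------------

@dataclass
class DwellSet:
    """Dwell positions of one needle channel, spaced along the fitted curve."""

    needle_id: int
    positions: np.ndarray  # (n, 3) mm, first position nearest the tip
    times: np.ndarray  # seconds
    step_mm: float
    offset_mm: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("positions and times must have equal length")
        if np.any(self.times < 0):
            raise ValueError("dwell times must be >= 0")

    def to_dict(self) -> dict:
        return {
            "needle_id": int(self.needle_id),
            "positions_mm": self.positions.tolist(),
            "times_s": self.times.tolist(),
            "step_mm": float(self.step_mm),
            "offset_mm": float(self.offset_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DwellSet":
        missing = [k for k in ("needle_id", "positions_mm", "times_s", "step_mm", "offset_mm")
                   if k not in d]
        if missing:
            raise ValueError(f"dwell set is missing fields: {missing}")
        return cls(d["needle_id"], np.asarray(d["positions_mm"]),
                   np.asarray(d["times_s"]), d["step_mm"], d["offset_mm"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def label_needles(mask: Volume, min_voxels: int = 5) -> tuple[Volume, int]:
    """Label 26-connected components of a binary mask as needle instances.

    Components smaller than ``min_voxels`` are discarded as segmentation
    noise; survivors are relabeled 1..K.  An empty mask yields K=0 with a
    warning rather than an error.
    """
    binary = np.asarray(mask.data) > 0
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n == 0:
        warnings.warn("label_needles: empty mask, no needle instances found")
        return Volume(labels.astype(np.int16), mask.spacing, mask.origin), 0
    counts = np.bincount(labels.ravel())
    keep = [lab for lab in range(1, n + 1) if counts[lab] >= min_voxels]
    out = np.zeros_like(labels, dtype=np.int16)
    for new, lab in enumerate(keep, start=1):
        out[labels == lab] = new
    if not keep:
        warnings.warn("label_needles: all components below the size threshold")
    return Volume(out, mask.spacing, mask.origin), len(keep)


def extract_centerline(
    instance: Volume,
    label: int = 1,
    needle_diameter_mm: float = 1.5,
) -> tuple[np.ndarray, bool]:
    """Per-slice centroid centerline of one labeled instance, in mm.

    For every z-slice intersecting the instance the unweighted centroid of
    its voxels is converted to world coordinates; points are ordered by z.
    Returns ``(points, merged_flag)`` where the flag marks an implausible
    in-plane jump (> 2x needle diameter between consecutive slices), the
    signature of touching needles merged into one component.
    """
    sel = np.asarray(instance.data) == label
    if not sel.any():
        raise ValueError(f"instance label {label} is empty")
    ks = np.unique(np.argwhere(sel)[:, 2])
    if ks.size < 2:
        raise ValueError(f"instance label {label} spans {ks.size} slice(s); not a needle")
    sx, sy, sz = instance.spacing
    ox, oy, oz = instance.origin
    pts = []
    for k in ks:
        ij = np.argwhere(sel[:, :, k])
        ci, cj = ij.mean(axis=0)
        pts.append((ox + ci * sx, oy + cj * sy, oz + k * sz))
    pts = np.asarray(pts)
    jumps = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    merged = bool(np.any(jumps > 2.0 * needle_diameter_mm))
    if merged:
        warnings.warn(
            f"instance {label}: in-plane centroid jump {jumps.max():.1f} mm exceeds "
            f"2x needle diameter; possible merged/touching needles"
        )
    return pts, merged


def fit_trajectory(
    points: np.ndarray,
    degree: int = 3,
    tip_extrapolation_mm: float = 0.0,
    merged_flag: bool = False,
) -> Trajectory:
    """Least-squares polynomial fit x(z), y(z) through ordered centerline points.

    The low-degree fit removes the systematic per-slice quantization error
    of centroid extraction.  ``points`` are re-evaluated on the fitted
    curve at each input z.  The tip is the fitted point at the deepest z,
    extrapolated by ``tip_extrapolation_mm`` beyond the last mask slice
    (the digitization pipeline passes half a slice thickness, correcting
    the slice quantization of the true tip).  Arc length is computed by
    numerical quadrature along the fitted curve.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    z = points[:, 2]
    if np.unique(z).size < 2:
        raise ValueError("all points lie in one slice; cannot fit a trajectory")
    deg = min(degree, np.unique(z).size - 1)
    # fit on centered/scaled z for conditioning, then expand to plain z
    zc, zs = z.mean(), max(z.std(), 1e-9)
    t = (z - zc) / zs
    cx_t = np.polynomial.polynomial.polyfit(t, points[:, 0], deg)
    cy_t = np.polynomial.polynomial.polyfit(t, points[:, 1], deg)
    shift = np.polynomial.polynomial.Polynomial([-zc / zs, 1.0 / zs])
    poly_x = np.polynomial.polynomial.Polynomial(cx_t)(shift).coef
    poly_y = np.polynomial.polynomial.Polynomial(cy_t)(shift).coef
    z_tip = float(z[-1] + tip_extrapolation_mm)
    x_fit = np.polyval(poly_x[::-1], z)
    y_fit = np.polyval(poly_y[::-1], z)
    pts_fit = np.stack([x_fit, y_fit, z], axis=1)
    tip = (float(np.polyval(poly_x[::-1], z_tip)),
           float(np.polyval(poly_y[::-1], z_tip)), z_tip)
    traj = Trajectory(pts_fit, poly_x, poly_y, tip, 0.0, merged_flag=merged_flag)
    _, s = traj.arc_table()
    traj.length_mm = float(s[-1])
    return traj


def sample_dwells(
    traj: Trajectory,
    step_mm: float = 2.5,
    offset_mm: float = 0.0,
    n_dwells: int = 5,
    dwell_time_s: float | np.ndarray = 10.0,
    needle_id: int = 0,
) -> DwellSet:
    """Place dwell positions along the fitted curve, walking from the tip.

    Dwell k sits at arc length ``offset_mm + k*step_mm`` from the tip
    toward the entry point.  Positions are solved by inverting the
    cumulative arc-length quadrature table (resolution well under 0.01 mm
    at the default sampling).
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    if offset_mm < 0:
        raise ValueError("offset_mm must be >= 0")
    if n_dwells < 1:
        raise ValueError("n_dwells must be >= 1")
    needed = offset_mm + (n_dwells - 1) * step_mm
    if needed > traj.length_mm + 1e-9:
        raise ValueError(
            f"needle {needle_id} (tip {traj.tip}): {n_dwells} dwells at step "
            f"{step_mm} mm with offset {offset_mm} mm need {needed:.1f} mm but the "
            f"needle is only {traj.length_mm:.1f} mm long"
        )
    zgrid, s = traj.arc_table()
    s_tip = s[-1]
    targets = s_tip - (offset_mm + step_mm * np.arange(n_dwells))
    z_at = np.interp(targets, s, zgrid)
    xy = traj.xy_at(z_at)
    positions = np.column_stack([xy, z_at])
    times = np.broadcast_to(np.asarray(dwell_time_s, dtype=float), (n_dwells,)).copy()
    return DwellSet(needle_id=needle_id, positions=positions, times=times,
                    step_mm=step_mm, offset_mm=offset_mm)


def match_needles(
    pred: list[Trajectory], truth: list[Trajectory]
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one needle assignment minimizing mean in-plane curve distance.

    Returns ``(pairs, false_positives, false_negatives)`` where pairs are
    (pred index, truth index); extras on either side are reported, not
    paired.  The cost between two trajectories is the mean in-plane
    distance of their fitted curves over the overlap of their z ranges
    (prohibitive when the ranges are disjoint).
    """
    if not pred or not truth:
        raise ValueError("both trajectory lists must be nonempty")
    big = 1e9
    cost = np.full((len(pred), len(truth)), big)
    for i, p in enumerate(pred):
        for j, t in enumerate(truth):
            lo = max(p.z_range[0], t.z_range[0])
            hi = min(p.z_range[1], t.z_range[1])
            if hi <= lo:
                continue
            z = np.linspace(lo, hi, 32)
            d = np.linalg.norm(p.xy_at(z) - t.xy_at(z), axis=1)
            cost[i, j] = float(d.mean())
    ri, ci = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(ri, ci) if cost[i, j] < big]
    matched_p = {i for i, _ in pairs}
    matched_t = {j for _, j in pairs}
    fp = [i for i in range(len(pred)) if i not in matched_p]
    fn = [j for j in range(len(truth)) if j not in matched_t]
    return pairs, fp, fn


def digitize_mask(
    mask: Volume,
    degree: int = 3,
    min_voxels: int = 5,
    needle_diameter_mm: float = 1.5,
) -> list[Trajectory]:
    """Full digitization of a binary needle mask into fitted trajectories.

    Labels instances, extracts per-slice-centroid centerlines, fits
    polynomials, and extrapolates each tip by half a slice thickness to
    compensate tip quantization by the slice grid.  Instances flagged as
    merged keep their flag so evaluation can exclude them.
    """
    labeled, n = label_needles(mask, min_voxels=min_voxels)
    out: list[Trajectory] = []
    half_slice = mask.spacing[2] / 2.0
    for lab in range(1, n + 1):
        try:
            pts, merged = extract_centerline(labeled, lab, needle_diameter_mm)
        except ValueError as e:
            warnings.warn(f"skipping instance {lab}: {e}")
            continue
        out.append(fit_trajectory(pts, degree=degree,
                                  tip_extrapolation_mm=half_slice,
                                  merged_flag=merged))
    return out
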