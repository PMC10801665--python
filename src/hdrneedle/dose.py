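"""TG-43 point-source dose engine, DVH metrics, and plan comparison.

Dose to a point is the superposition over all dwell positions of

    D(r) = S_K * Lambda * (r0 / r)^2 * g(r) * phi_an(r) * t

with S_K the air-kerma strength (U), Lambda the dose-rate constant
(cGy h^-1 U^-1), r0 = 10 mm the reference distance, g(r) the radial dose
function and phi_an(r) the 1-D anisotropy function (both tabulated and
linearly interpolated), and t the dwell time in seconds.  This is the 1-D
point-source specialization of the TG-43 formalism: the line-source
geometry factor and the 2-D anisotropy F(r, theta) are intentionally out
of scope, which keeps the engine closed-form testable (unity tables turn
it into a pure inverse-square law).

DVH metrics are computed by exact voxel accounting: D90/D100 for the
target and D2cc for organs at risk, plus the signed absolute and relative
differences between a manually and an automatically digitized plan.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import Volume
from .digitize import DwellSet

#: minimum source-point distance (mm); TG-43 tables are undefined at r -> 0
MIN_RADIUS_MM = 0.5

#: seconds per hour x cGy per Gy — converts S_K*Lambda*t to Gy
_CGY_H_TO_GY_S = 1.0 / 3600.0 / 100.0


@dataclass
class SourceModel:
    """A 1-D TG-43 source description with tabulated g(r) and phi_an(r).

    ``air_kerma_strength`` is in U (uGy m^2/h = cGy cm^2/h);
    ``dose_rate_constant`` in cGy/(h U); tables are (r_mm, value) pairs
    with strictly increasing radii; ``reference_r0`` is 10 mm.
    """

    air_kerma_strength: float
    dose_rate_constant: float
    radial_dose: np.ndarray
    anisotropy: np.ndarray
    reference_r0: float = 10.0
    name: str = "custom"

    def __post_init__(self) -> None:
        self.radial_dose = np.asarray(self.radial_dose, dtype=float).reshape(-1, 2)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float).reshape(-1, 2)
        for tab, label in ((self.radial_dose, "radial_dose"), (self.anisotropy, "anisotropy")):
            if np.any(np.diff(tab[:, 0]) <= 0):
                raise ValueError(f"{label} table radii must be strictly increasing")
        g_r0 = float(np.interp(self.reference_r0, self.radial_dose[:, 0],
                               self.radial_dose[:, 1]))
        if abs(g_r0 - 1.0) > 1e-3:
            raise ValueError(f"g(r0={self.reference_r0} mm) must be 1, got {g_r0}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def unity(cls, air_kerma_strength: float = 1000.0,
              dose_rate_constant: float = 1.0,
              r_max_mm: float = 1000.0) -> "SourceModel":
        """Analytic test source: g = phi = 1 → pure inverse-square law."""
        tab = np.array([[MIN_RADIUS_MM, 1.0], [r_max_mm, 1.0]])
        return cls(air_kerma_strength, dose_rate_constant, tab, tab.copy(),
                   name="unity")

    @classmethod
    def generic_ir192(cls, air_kerma_strength: float = 40800.0) -> "SourceModel":
        """Bundled generic Ir-192 source (default S_K ~ 10 Ci)."""
        ref = importlib.resources.files("hdrneedle").joinpath("data/ir192_generic.csv")
        rows = []
        lam = 1.109
        r0 = 10.0
        for line in ref.read_text().splitlines():
            line = line.strip()
            if line.startswith("# dose_rate_constant_cgy_per_h_u"):
                lam = float(line.split("=")[1])
            elif line.startswith("# reference_r0_mm"):
                r0 = float(line.split("=")[1])
            elif not line or line.startswith("#") or line.startswith("r_mm"):
                continue
            else:
                rows.append([float(v) for v in line.split(",")])
        arr = np.asarray(rows)
        return cls(air_kerma_strength, lam, arr[:, [0, 1]], arr[:, [0, 2]],
                   reference_r0=r0, name="generic_ir192")

    def to_dict(self) -> dict:
        return {
            "air_kerma_strength_u": self.air_kerma_strength,
            "dose_rate_constant_cgy_h_u": self.dose_rate_constant,
            "radial_dose_table": self.radial_dose.tolist(),
            "anisotropy_table": self.anisotropy.tolist(),
            "reference_r0_mm": self.reference_r0,
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SourceModel":
        return cls(d["air_kerma_strength_u"], d["dose_rate_constant_cgy_h_u"],
                   np.asarray(d["radial_dose_table"]), np.asarray(d["anisotropy_table"]),
                   d.get("reference_r0_mm", 10.0), d.get("name", "custom"))


@dataclass
class Plan:
    """An HDR plan: needle channels with dwells, prescription, and source."""

    needles: list[DwellSet]
    source: SourceModel
    prescription_dose_gy: float = 6.0

    def __post_init__(self) -> None:
        if not self.needles:
            raise ValueError("a plan needs at least one needle")

    def all_dwells(self) -> tuple[np.ndarray, np.ndarray]:
        pos = np.concatenate([n.positions for n in self.needles], axis=0)
        t = np.concatenate([n.times for n in self.needles])
        return pos, t


@dataclass
class DVHResult:
    """Cumulative DVH of one structure plus the scalar metrics of interest."""

    dose_axis: np.ndarray
    cumulative_volume: np.ndarray  # fraction of structure receiving >= dose
    d90: float
    d100: float
    d2cc: float | None
    structure_volume_cc: float

    def to_dict(self) -> dict:
        return {
            "d90_gy": self.d90,
            "d100_gy": self.d100,
            "d2cc_gy": self.d2cc,
            "structure_volume_cc": self.structure_volume_cc,
            "dose_axis_gy": self.dose_axis.tolist(),
            "cumulative_volume": self.cumulative_volume.tolist(),
        }


# ---------------------------------------------------------------------------
# dose computation
# ---------------------------------------------------------------------------

def _dose_from_dwells(points: np.ndarray, pos: np.ndarray, times: np.ndarray,
                      src: SourceModel, allow_extrapolation: bool) -> np.ndarray:
    """Vectorized TG-43 point-source sum; points (N,3), dwells (M,3)."""
    r = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
    n_clamped = int((r < MIN_RADIUS_MM).sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} point-dwell distance(s) below {MIN_RADIUS_MM} mm clamped"
        )
        r = np.maximum(r, MIN_RADIUS_MM)
    r_max = min(src.radial_dose[-1, 0], src.anisotropy[-1, 0])
    if not allow_extrapolation and r.max() > r_max + 1e-9:
        raise ValueError(
            f"distance {r.max():.1f} mm exceeds the source table range ({r_max:.1f} mm); "
            "pass allow_extrapolation=True to clamp to the last table value"
        )
    g = np.interp(r, src.radial_dose[:, 0], src.radial_dose[:, 1])
    phi = np.interp(r, src.anisotropy[:, 0], src.anisotropy[:, 1])
    rate = (src.air_kerma_strength * src.dose_rate_constant
            * (src.reference_r0 / r) ** 2 * g * phi)  # cGy/h per dwell
    return (rate * times[None, :]).sum(axis=1) * _CGY_H_TO_GY_S


def dose_at_point(point, plan: Plan, allow_extrapolation: bool = False) -> float:
    """Total dose (Gy) at a mm point from all dwells of a plan."""
    pos, t = plan.all_dwells()
    pt = np.asarray(point, dtype=float).reshape(1, 3)
    return float(_dose_from_dwells(pt, pos, t, plan.source, allow_extrapolation)[0])


def dose_grid(grid: Volume, plan: Plan, allow_extrapolation: bool = True) -> Volume:
    """Dose (Gy) evaluated at every voxel center of ``grid``'s geometry.

    Table extrapolation defaults to clamped here because grid corners
    routinely exceed clinical table ranges.
    """
    pos, t = plan.all_dwells()
    nx, ny, nz = grid.shape
    idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                               indexing="ij"), axis=-1).reshape(-1, 3)
    pts = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
    dose = np.zeros(len(pts))
    chunk = 65536  # bound the (points x dwells) distance matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamp warnings per chunk are noise here
        for lo in range(0, len(pts), chunk):
            dose[lo:lo + chunk] = _dose_from_dwells(
                pts[lo:lo + chunk], pos, t, plan.source, allow_extrapolation
            )
    return Volume(dose.reshape(grid.shape), grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

def compute_dvh(dose: Volume, structure: Volume, bin_width_gy: float = 0.01) -> DVHResult:
    """Cumulative DVH over a structure mask with D90/D100/D2cc.

    Dx% is the dose received by at least x% of the structure volume,
    obtained by inverting the cumulative curve with linear interpolation;
    D2cc is the minimum dose of the hottest 2 cm^3.  A structure smaller
    than 2 cc reports D2cc as None (undefined), not an error.
    """
    dose.require_same_grid(structure)
    sel = np.asarray(structure.data) > 0
    if not sel.any():
        raise ValueError("structure mask is empty")
    doses = np.asarray(dose.data, dtype=float)[sel]
    voxel_cc = dose.voxel_volume_mm3 / 1000.0
    vol_cc = doses.size * voxel_cc

    dmax = float(doses.max())
    edges = np.arange(0.0, dmax + 2 * bin_width_gy, bin_width_gy)
    # fraction of structure receiving >= dose level
    cum = 1.0 - np.searchsorted(np.sort(doses), edges, side="left") / doses.size

    def dx(fraction: float) -> float:
        # largest dose level still covering `fraction` of the volume
        idx = np.nonzero(cum >= fraction - 1e-12)[0]
        if idx.size == 0:
            return 0.0
        i = idx[-1]
        if i + 1 >= edges.size or cum[i] == cum[i + 1]:
            return float(edges[i])
        f = (cum[i] - fraction) / (cum[i] - cum[i + 1])
        return float(edges[i] + f * bin_width_gy)

    d90 = dx(0.90)
    d100 = float(doses.min())
    if vol_cc < 2.0:
        warnings.warn(
            f"structure volume {vol_cc:.2f} cc < 2 cc; D2cc undefined"
        )
        d2cc = None
    else:
        d2cc = dx(2.0 / vol_cc)
    return DVHResult(dose_axis=edges, cumulative_volume=cum, d90=d90, d100=d100,
                     d2cc=d2cc, structure_volume_cc=vol_cc)


def dose_difference(manual: float, automatic: float,
                    relative: bool = True) -> tuple[float, float | None]:
    """Signed DVH-metric difference between manual and automatic plans.

    Returns ``(manual - automatic, (manual - automatic)/manual)``; the
    relative part is None when not requested and an error when requested
    with manual = 0.
    """
    diff = manual - automatic
    if not relative:
        return diff, None
    if manual == 0:
        raise ValueError("relative dose difference undefined for manual metric = 0")
    return diff, diff / manual
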