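"""Synthetic CT-like needle phantom with analytic ground truth.

Emulates the imaging situation of CT-guided interstitial HDR brachytherapy
of the pelvis: a soft-tissue body on a coarse-slice CT grid (default
0.8 mm in-plane, 5 mm slices), pierced by 3-6 near-parallel trocar steel
needles of 1.5 mm diameter that appear as thin, very bright tubes, with
optional streak artifacts radiating from the metal cross-sections.  An
HR-CTV ellipsoid encloses the needle bundle and two organ-at-risk
structures (bladder-like, rectum-like) sit adjacent to it.

Each needle's centerline is an analytic polynomial curve x(z), y(z) of
degree <= 2 (trocar needles are nearly straight), so every downstream
digitization step can be scored against closed-form truth.  All randomness
is drawn from a single integer seed; identical configs give bit-identical
phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Volume
from .digitize import Trajectory, trajectory_from_polynomial


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration cannot be realized."""


@dataclass
class PhantomConfig:
    """Geometry and intensity model of the synthetic needle phantom.

    Spacings are mm per voxel; intensities are HU-like.  ``curvature`` is
    the maximum in-plane bowing (mm) of a needle over its length;
    ``max_tilt_deg`` bounds the linear tilt of needles away from the slice
    axis.  ``min_separation_mm`` is the minimum in-plane distance between
    needle entry points (0 permits touching/crossing needles, the hard
    clinical case).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing_mm: tuple[float, float, float] = (0.8, 0.8, 5.0)
    n_needles: int = 4
    needle_radius_mm: float = 0.75
    needle_intensity: float = 3000.0
    tissue_intensity_mean: float = 40.0
    tissue_intensity_sd: float = 12.0
    curvature: float = 1.5
    max_tilt_deg: float = 5.0
    min_separation_mm: float = 3.0
    tip_depth_fraction: tuple[float, float] = (0.7, 0.95)
    artifact_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise PhantomConfigError(f"all grid dimensions must be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomConfigError(f"all spacings must be > 0, got {self.spacing_mm}")
        if self.n_needles < 1:
            raise PhantomConfigError("n_needles must be >= 1")
        if self.needle_radius_mm <= 0:
            raise PhantomConfigError("needle_radius_mm must be > 0")
        if self.artifact_strength < 0:
            raise PhantomConfigError("artifact_strength must be >= 0")


@dataclass
class GroundTruth:
    """Analytic ground truth accompanying a phantom volume.

    ``instance_mask`` labels needle voxels 1..n_needles; ``centerlines``
    hold the analytic trajectories (one per needle, same order as labels);
    ``structures`` maps names ('hrctv', 'bladder', 'rectum') to binary
    masks on the same grid.
    """

    instance_mask: Volume
    centerlines: list[Trajectory]
    structures: dict[str, Volume]

    @property
    def binary_mask(self) -> Volume:
        return Volume((self.instance_mask.data > 0).astype(np.uint8),
                      self.instance_mask.spacing, self.instance_mask.origin)


def _sample_centerlines(cfg: PhantomConfig, rng: np.random.Generator):
    """Draw per-needle polynomials x(z), y(z) = c0 + c1*z + c2*z^2 (z in mm)."""
    nx, ny, nz = cfg.grid_shape
    sx, sy, sz = cfg.spacing_mm
    extent_x, extent_y = nx * sx, ny * sy
    z_top = (nz - 1) * sz
    # entry points inside an inner ellipse of the body cross-section
    cx, cy = extent_x / 2, extent_y / 2
    ax_in, ay_in = 0.28 * extent_x, 0.28 * extent_y
    entries: list[tuple[float, float]] = []
    max_tries = 2000
    for _ in range(max_tries):
        if len(entries) == cfg.n_needles:
            break
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 1))
        pt = (cx + ax_in * rad * np.cos(ang), cy + ay_in * rad * np.sin(ang))
        if all(np.hypot(pt[0] - e[0], pt[1] - e[1]) >= cfg.min_separation_mm for e in entries):
            entries.append(pt)
    if len(entries) < cfg.n_needles:
        raise PhantomConfigError(
            f"cannot place {cfg.n_needles} needles with min separation "
            f"{cfg.min_separation_mm} mm in a {extent_x:.0f}x{extent_y:.0f} mm grid"
        )
    curves = []
    tilt_max = np.tan(np.deg2rad(cfg.max_tilt_deg))
    for ex, ey in entries:
        tip_z = rng.uniform(*cfg.tip_depth_fraction) * z_top
        b = rng.uniform(-tilt_max, tilt_max, size=2)
        # quadratic bowing with zero deviation at both ends of the shaft:
        # x(z) = ex + b*z + c2*z*(z - tip_z); peak bow is |c2|*(tip_z/2)^2
        if cfg.curvature > 0 and tip_z > 0:
            amp = rng.uniform(0, cfg.curvature, size=2) * rng.choice([-1, 1], size=2)
            c2 = amp / (tip_z / 2) ** 2
        else:
            c2 = np.zeros(2)
        poly_x = np.array([ex, b[0] - c2[0] * tip_z, c2[0]])
        poly_y = np.array([ey, b[1] - c2[1] * tip_z, c2[1]])
        curves.append((poly_x, poly_y, 0.0, tip_z))
    return curves


def _rasterize_needles(cfg: PhantomConfig, curves) -> np.ndarray:
    """Instance-label voxels whose in-plane center lies within the tube radius."""
    nx, ny, nz = cfg.grid_shape
    sx, sy, sz = cfg.spacing_mm
    mask = np.zeros(cfg.grid_shape, dtype=np.int16)
    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    xv, yv = np.meshgrid(xs, ys, indexing="ij")
    for label, (px, py, z0, z1) in enumerate(curves, start=1):
        for k in range(nz):
            z = k * sz
            if z < z0 or z > z1:
                continue
            cxz = px[0] + px[1] * z + px[2] * z * z
            cyz = py[0] + py[1] * z + py[2] * z * z
            d2 = (xv - cxz) ** 2 + (yv - cyz) ** 2
            sel = d2 <= cfg.needle_radius_mm ** 2
            # later labels win on overlap (touching/crossing permitted)
            mask[:, :, k][sel] = label
    return mask


def _ellipsoid_mask(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xv, yv, zv = np.meshgrid(*coords, indexing="ij")
    return ((xv - center_mm[0]) ** 2 / semi_mm[0] ** 2
            + (yv - center_mm[1]) ** 2 / semi_mm[1] ** 2
            + (zv - center_mm[2]) ** 2 / semi_mm[2] ** 2) <= 1.0


def _make_structures(cfg: PhantomConfig, needle_mask: np.ndarray) -> dict[str, np.ndarray]:
    nx, ny, nz = cfg.grid_shape
    sx, sy, sz = cfg.spacing_mm
    ex, ey, ez = nx * sx, ny * sy, (nz - 1) * sz
    idx = np.argwhere(needle_mask > 0)
    world = idx * np.array(cfg.spacing_mm)
    lo, hi = world.min(axis=0), world.max(axis=0)
    center = (lo + hi) / 2
    semi = np.maximum((hi - lo) / 2 + [2 * sx, 2 * sy, 0.8 * sz], 1e-3)
    # inflate so every needle voxel center is strictly inside the ellipsoid
    # (a bounding-box ellipsoid alone misses the box corners)
    radii = np.sqrt((((world - center) / semi) ** 2).sum(axis=1))
    semi *= max(1.0, float(radii.max())) * 1.02
    hrctv = _ellipsoid_mask(cfg.grid_shape, cfg.spacing_mm, center, semi)
    # bladder-like OAR anterior (toward -y), rectum-like posterior (+y)
    oar_semi = np.array([0.18 * ex, 0.12 * ey, 0.4 * ez])
    bladder = _ellipsoid_mask(cfg.grid_shape, cfg.spacing_mm,
                              [center[0], max(center[1] - semi[1] - oar_semi[1] - sy, oar_semi[1]),
                               center[2]], oar_semi)
    rectum = _ellipsoid_mask(cfg.grid_shape, cfg.spacing_mm,
                             [center[0], min(center[1] + semi[1] + oar_semi[1] + sy,
                                             ey - oar_semi[1]), center[2]], oar_semi)
    # keep structures mutually disjoint, priority hrctv > bladder > rectum
    bladder &= ~hrctv
    rectum &= ~hrctv & ~bladder
    return {"hrctv": hrctv, "bladder": bladder, "rectum": rectum}


def make_phantom(config: PhantomConfig) -> tuple[Volume, GroundTruth]:
    """Generate a seeded CT-like phantom and its analytic ground truth.

    The body is a soft-tissue ellipse (air outside), needles are bright
    tubes around polynomial centerlines, and structure masks are ellipsoids
    placed around/near the needle bundle.  Deterministic per config.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nx, ny, nz = cfg.grid_shape

    curves = _sample_centerlines(cfg, rng)
    instance = _rasterize_needles(cfg, curves)
    for label in range(1, cfg.n_needles + 1):
        n_slices = np.unique(np.argwhere(instance == label)[:, 2]).size
        if n_slices < 2:
            raise PhantomConfigError(
                f"needle {label} intersects {n_slices} slice(s); grid too coarse or "
                f"radius {cfg.needle_radius_mm} mm too small for spacing {cfg.spacing_mm}"
            )

    # body: soft tissue inside an ellipse, air outside
    xs = (np.arange(nx) - nx / 2 + 0.5) / (nx / 2)
    ys = (np.arange(ny) - ny / 2 + 0.5) / (ny / 2)
    xv, yv = np.meshgrid(xs, ys, indexing="ij")
    body2d = (xv ** 2 / 0.9 ** 2 + yv ** 2 / 0.9 ** 2) <= 1.0
    body = np.repeat(body2d[:, :, None], nz, axis=2)

    data = np.full(cfg.grid_shape, -1000.0, dtype=np.float32)
    tissue = rng.normal(cfg.tissue_intensity_mean, cfg.tissue_intensity_sd,
                        size=cfg.grid_shape).astype(np.float32)
    data[body] = tissue[body]
    data[instance > 0] = cfg.needle_intensity

    volume = Volume(data, cfg.spacing_mm)
    structures = {
        name: Volume(m.astype(np.uint8), cfg.spacing_mm)
        for name, m in _make_structures(cfg, instance).items()
    }
    slice_z = np.arange(nz) * cfg.spacing_mm[2]
    centerlines = [
        trajectory_from_polynomial(px, py, z0, z1, z_samples=slice_z)
        for (px, py, z0, z1) in curves
    ]
    truth = GroundTruth(
        instance_mask=Volume(instance, cfg.spacing_mm),
        centerlines=centerlines,
        structures=structures,
    )
    if cfg.artifact_strength > 0:
        volume = add_artifacts(volume, truth, cfg.artifact_strength, cfg.seed)
    return volume, truth


def add_artifacts(volume: Volume, truth: GroundTruth, strength: float,
                  seed: int) -> Volume:
    """Add radial streak perturbations emanating from needle cross-sections.

    Streaks are modelled per slice as angular cosine lobes around each
    needle center with a 1/(1+r) radial falloff — a lightweight stand-in
    for metal streaks, linear in ``strength``.  Needle-core voxels are left
    untouched so cores keep their full intensity.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    nx, ny, nz = volume.shape
    sx, sy, _ = volume.spacing
    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    xv, yv = np.meshgrid(xs, ys, indexing="ij")
    pert = np.zeros(volume.shape, dtype=np.float32)
    for traj in truth.centerlines:
        n_spokes = int(rng.integers(6, 12))
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        zs = np.array([p[2] for p in traj.points])
        for k in range(nz):
            z = volume.slice_z_mm(k)
            if z < zs.min() - 1e-9 or z > zs.max() + 1e-9:
                continue
            cxz = float(np.polyval(traj.poly_x[::-1], z))
            cyz = float(np.polyval(traj.poly_y[::-1], z))
            dx, dy = xv - cxz, yv - cyz
            r = np.hypot(dx, dy)
            theta = np.arctan2(dy, dx)
            pert[:, :, k] += (amp * np.cos(n_spokes * theta + phase)
                              / (1.0 + r)).astype(np.float32)
    core = truth.instance_mask.data > 0
    pert[core] = 0.0
    out = volume.copy()
    out.data = out.data + strength * pert
    return out
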