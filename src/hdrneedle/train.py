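"""Training recipe: augmentation, cropping, the Adam loop, and inference.

The recipe mirrors standard practice for volumetric needle segmentation
with scarce data: paired geometric augmentation (in-plane rotation,
horizontal/vertical flips, isotropic in-plane scaling) applied identically
to image and mask, central in-plane cropping for efficiency, Adam at
learning rate 5e-4 with batch size 1, and the soft Dice loss to counter
the extreme foreground/background imbalance of thin needles.

Rotations and scalings are in-plane only (about the slice axis): needles
are near-axial, and out-of-plane resampling would break the slice-wise
digitization downstream.  CT intensities are normalized by a fixed factor
of 1000 before entering the network, keeping metal at O(1) activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import Volume
from .nn import Adam, LossConfig, SegmentationModel, soft_dice_loss

#: fixed intensity scale between HU-like values and network inputs
INTENSITY_SCALE = 1000.0


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    optimizer: str = "adam"
    max_epochs: int = 200
    batch_size: int = 1
    augment_rotation: bool = True
    augment_flip_horizontal: bool = True
    augment_flip_vertical: bool = True
    augment_scaling: bool = True
    rotation_range_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    crop_size: tuple[int, int] = (64, 64)
    threshold: float = 0.5
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if min(self.scale_range) <= 0:
            raise ValueError("scale_range bounds must be > 0")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    @property
    def augmentation_enabled(self) -> bool:
        return (self.augment_rotation or self.augment_flip_horizontal
                or self.augment_flip_vertical or self.augment_scaling)


@dataclass
class TrainHistory:
    """Per-epoch training curve (one record per completed epoch)."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)

    def append(self, epoch: int, tl: float, vl: float, vd: float) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(tl)
        self.val_loss.append(vl)
        self.val_dice.append(vd)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": self.epochs,
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_dice": self.val_dice,
        })


# ---------------------------------------------------------------------------
# geometric augmentation
# ---------------------------------------------------------------------------

def _inplane_affine(data: np.ndarray, angle_deg: float, scale: float,
                    order: int, cval: float) -> np.ndarray:
    """Rotate/scale every slice about the in-plane volume center."""
    if angle_deg == 0.0 and scale == 1.0:
        return data.copy()
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    m2 = rot / scale  # maps output coords to input coords
    m = np.eye(3)
    m[:2, :2] = m2
    center = (np.asarray(data.shape, dtype=float) - 1) / 2
    offset = center - m @ center
    return ndimage.affine_transform(data, m, offset=offset, order=order,
                                    mode="constant", cval=cval,
                                    prefilter=False)


def augment_pair(volume: Volume, mask: Volume, cfg: TrainConfig,
                 seed: int) -> tuple[Volume, Volume]:
    """Apply one seeded draw of the augmentation transform to image + mask.

    The identical spatial transform hits both grids; the image is
    resampled with linear interpolation, the mask with nearest neighbor so
    it stays binary.  Flips are about the volume center; rotation and
    scaling are in-plane.  Grid metadata (spacing/origin) is unchanged.
    """
    volume.require_same_grid(mask)
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg)) \
        if cfg.augment_rotation else 0.0
    flip_h = bool(rng.random() < 0.5) if cfg.augment_flip_horizontal else False
    flip_v = bool(rng.random() < 0.5) if cfg.augment_flip_vertical else False
    scale = float(rng.uniform(*cfg.scale_range)) if cfg.augment_scaling else 1.0

    vdata = np.asarray(volume.data, dtype=np.float32)
    mdata = np.asarray(mask.data)
    background = float(vdata.min())
    vout = _inplane_affine(vdata, angle, scale, order=1, cval=background)
    mout = _inplane_affine(mdata.astype(np.float32), angle, scale, order=0, cval=0.0)
    if flip_h:
        vout = vout[::-1, :, :]
        mout = mout[::-1, :, :]
    if flip_v:
        vout = vout[:, ::-1, :]
        mout = mout[:, ::-1, :]
    return (Volume(np.ascontiguousarray(vout), volume.spacing, volume.origin),
            Volume(np.ascontiguousarray(mout).astype(mdata.dtype), mask.spacing, mask.origin))


def crop_center(volume: Volume, size: tuple[int, int]) -> Volume:
    """Central in-plane crop keeping all slices; world coordinates preserved.

    The origin shifts by the crop offset times the spacing, so any retained
    voxel keeps its world position.
    """
    tx, ty = size
    nx, ny, _ = volume.shape
    if tx > nx or ty > ny:
        raise ValueError(f"crop size {size} exceeds in-plane shape {(nx, ny)}")
    x0 = (nx - tx) // 2
    y0 = (ny - ty) // 2
    data = volume.data[x0:x0 + tx, y0:y0 + ty, :]
    ox, oy, oz = volume.origin
    sx, sy, _ = volume.spacing
    return Volume(np.ascontiguousarray(data), volume.spacing,
                  (ox + x0 * sx, oy + y0 * sy, oz))


# ---------------------------------------------------------------------------
# tensor plumbing
# ---------------------------------------------------------------------------

def _to_net(data: np.ndarray) -> np.ndarray:
    """(nx, ny, nz) volume -> (1, nz, ny, nx) float32 network tensor.

    The network is axis-agnostic; slice-major order just puts the largest
    contiguous axis innermost for the convolution kernels.
    """
    return np.ascontiguousarray(data.T, dtype=np.float32)[None]


def _from_net(t: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(t[0].T)


def _binary_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = int(np.logical_and(pred, truth).sum())
    denom = int(pred.sum()) + int(truth.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom


# ---------------------------------------------------------------------------
# training loop and inference
# ---------------------------------------------------------------------------

def train_model(
    model: SegmentationModel,
    train_set: list[tuple[Volume, Volume]],
    val_set: list[tuple[Volume, Volume]],
    cfg: TrainConfig,
    log_fn=None,
) -> tuple[SegmentationModel, TrainHistory]:
    """Adam training of the segmentation model on (volume, mask) pairs.

    Minimizes the soft Dice loss with the configured recipe; records one
    history row per epoch (mean train loss, validation loss, validation
    Dice at the binarization threshold).  All randomness (shuffling,
    augmentation draws) derives from ``cfg.seed``, so a run is reproducible
    on one device.  Non-finite loss aborts with a diagnostic.
    """
    if not train_set:
        raise ValueError("training set must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    history = TrainHistory()

    def prepare(vol: Volume, mask: Volume, aug_seed: int | None):
        if aug_seed is not None and cfg.augmentation_enabled:
            vol, mask = augment_pair(vol, mask, cfg, aug_seed)
        vol = crop_center(vol, cfg.crop_size)
        mask = crop_center(mask, cfg.crop_size)
        x = _to_net(vol.data) / INTENSITY_SCALE
        t = _to_net((mask.data > 0).astype(np.float32))
        return x, t

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        for step, idx in enumerate(order):
            aug_seed = int(rng.integers(2 ** 31))
            x, t = prepare(*train_set[idx], aug_seed)
            prob = model.forward(x)
            loss, grad = soft_dice_loss(prob, t, cfg.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, step {step}"
                )
            losses.append(loss)
            if step % cfg.batch_size == 0:
                model.zero_grad()
            model.backward(grad)
            if (step + 1) % cfg.batch_size == 0 or step == len(order) - 1:
                opt.step()
        val_losses, val_dices = [], []
        for vol, mask in val_set:
            x, t = prepare(vol, mask, None)
            prob = model.forward(x)
            vl, _ = soft_dice_loss(prob, t, cfg.loss)
            val_losses.append(vl)
            val_dices.append(_binary_dice(prob >= cfg.threshold, t > 0.5))
        vl = float(np.mean(val_losses)) if val_losses else float("nan")
        vd = float(np.mean(val_dices)) if val_dices else float("nan")
        tl = float(np.mean(losses))
        history.append(epoch, tl, vl, vd)
        if log_fn is not None:
            log_fn(f"epoch {epoch:3d}  train_loss {tl:.4f}  val_loss {vl:.4f}  "
                   f"val_dice {vd:.4f}")
    return model, history


def predict_mask(model: SegmentationModel, volume: Volume,
                 threshold: float = 0.5) -> Volume:
    """Segment a volume: sigmoid probabilities thresholded to a binary mask.

    Spatial dims are zero-padded up to the network's divisibility
    requirement and the prediction is cropped back, so the output grid
    equals the input grid.
    """
    div = 2 ** (model.config.depth - 1)
    x = _to_net(np.asarray(volume.data, dtype=np.float32)) / INTENSITY_SCALE
    pads = [(0, 0)]
    for s in x.shape[1:]:
        pads.append((0, (-s) % div))
    x_p = np.pad(x, pads) if any(p[1] for p in pads) else x
    prob = model.forward(x_p)
    sl = tuple(slice(0, s) for s in x.shape)
    prob = prob[sl]
    mask = (_from_net(prob) >= threshold).astype(np.uint8)
    return Volume(mask, volume.spacing, volume.origin)


def predict_probability(model: SegmentationModel, volume: Volume) -> Volume:
    """Raw per-voxel needle probabilities on the input grid."""
    div = 2 ** (model.config.depth - 1)
    x = _to_net(np.asarray(volume.data, dtype=np.float32)) / INTENSITY_SCALE
    pads = [(0, 0)]
    for s in x.shape[1:]:
        pads.append((0, (-s) % div))
    x_p = np.pad(x, pads) if any(p[1] for p in pads) else x
    prob = model.forward(x_p)
    sl = tuple(slice(0, s) for s in x.shape)
    return Volume(_from_net(prob[sl]), volume.spacing, volume.origin)
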