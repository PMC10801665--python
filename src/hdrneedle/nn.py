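"""Attention-gated 3D U-Net for needle segmentation, with soft Dice loss.

The segmentation network is an encoder--decoder 3D U-Net: per resolution
level two 3x3x3 convolutions (zero padding) each followed by group
normalization and ReLU, 2x max-pooling between encoder levels, stride-2
transposed convolutions in the decoder, skip concatenation, and a final
1x1x1 convolution with a sigmoid head.  Optionally, an additive attention
gate is applied to each encoder skip feature before concatenation: with
``x`` the fine-level feature map and ``g`` the coarser decoder gating
signal (upsampled to x's grid by trilinear interpolation),

    q     = psi( ReLU(W_x x + W_g g + b_xg) ) + b_psi
    alpha = sigmoid(q)

and the skip feature is scaled voxelwise by ``alpha`` in [0, 1].  All maps
W_x, W_g, psi are 1x1x1 convolutions, so the gate is a cheap per-voxel
additive attention that suppresses background and highlights thin
high-contrast structures such as needles.

Everything here -- layers, the attention gate, the U-Net, Adam and the soft
Dice loss -- is implemented directly on numpy arrays with hand-written
backward passes (direct numba kernels for the 3x3x3 convolutions, a
flat-offset BLAS formulation for the weight gradient).  Tensors are
channel-first without a batch axis, shape ``(C, D, H, W)``; the training
recipe uses batch size 1, so a batch axis would only add copies.
Correctness of every backward pass is established by finite-difference
gradient checks in the test suite, and the attention gate additionally by a
per-voxel loop oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numba
import numpy as np

FLOAT = np.float32


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    """Topology of the segmentation network.

    ``depth`` counts resolution levels (including the bottleneck);
    ``base_channels`` is the channel width at the finest level and doubles
    per level.  ``use_attention`` switches between the plain CNN and the
    CNN+AG variant.  ``gn_groups`` is the group count of group
    normalization; ``gn_encoder_only`` restricts normalization to the
    encoder (both placements are supported, the default normalizes encoder
    and decoder).
    """

    depth: int = 4
    base_channels: int = 16
    use_attention: bool = False
    gn_groups: int = 4
    gn_encoder_only: bool = False
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels % self.gn_groups != 0:
            raise ValueError(
                f"base_channels ({self.base_channels}) must be divisible by "
                f"gn_groups ({self.gn_groups})"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetConfig":
        return cls(**json.loads(text))


@dataclass
class LossConfig:
    """Soft Dice loss smoothing constant (prevents 0/0 on empty masks)."""

    epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def conv_layer_count(config: NetConfig) -> int:
    """Number of convolutional layers under the adopted counting convention.

    Counts the 3x3x3 convolutions of encoder and decoder and the stride-2
    up-convolutions; the final 1x1x1 head and the 1x1x1 maps inside
    attention gates are not counted.  With this convention a depth-5
    network has 2*5 + 3*4 = 22 convolutional layers.
    """
    return 2 * config.depth + 3 * (config.depth - 1)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

class Param:
    """A learnable tensor with accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=FLOAT)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(FLOAT)


# ---------------------------------------------------------------------------
# primitive ops (forward + backward)
# ---------------------------------------------------------------------------

@numba.njit(fastmath=True, boundscheck=False, cache=True)
def _conv3_fwd_kernel(xp, w, b, y):  # pragma: no cover - exercised via Conv3x3
    """y[co] = sum_ci w[co,ci] * xp[ci] (valid conv of a pre-padded input)."""
    co_n, ci_n = w.shape[0], w.shape[1]
    d, h, ww = y.shape[1], y.shape[2], y.shape[3]
    for i in range(d):
        for j in range(h):
            acc = np.zeros((co_n, ww), dtype=y.dtype)
            for ci in range(ci_n):
                for a in range(3):
                    for bb in range(3):
                        row = xp[ci, i + a, j + bb]
                        for co in range(co_n):
                            w0 = w[co, ci, a, bb, 0]
                            w1 = w[co, ci, a, bb, 1]
                            w2 = w[co, ci, a, bb, 2]
                            arow = acc[co]
                            for l in range(ww):
                                arow[l] += w0 * row[l] + w1 * row[l + 1] + w2 * row[l + 2]
            for co in range(co_n):
                bv = b[co]
                for l in range(ww):
                    y[co, i, j, l] = acc[co, l] + bv


def _conv3_dw(xp: np.ndarray, dy: np.ndarray, dw: np.ndarray) -> None:
    """dw[co,ci,a,b,c] += sum_n dy[co,n] * xp[ci, n + (a,b,c)].

    Computed as 27 small GEMMs on flat-offset views of the padded input:
    embedding dy into the padded geometry makes every kernel offset a plain
    linear shift of the flattened array, so each lag reduces to
    ``dy_pad @ shift(xp).T`` with a long contraction axis that BLAS handles
    efficiently.  The zero padding of dy_pad cancels out-of-range terms.
    """
    ci_n = xp.shape[0]
    co_n = dy.shape[0]
    dp, hp, wp = xp.shape[1:]
    d, h, w = dy.shape[1:]
    n_pad = dp * hp * wp
    dyp = np.zeros((co_n, dp, hp, wp), dtype=dy.dtype)
    dyp[:, 1:1 + d, 1:1 + h, 1:1 + w] = dy
    dypf = dyp.reshape(co_n, n_pad)
    xpf = xp.reshape(ci_n, n_pad)
    for a in range(3):
        for b in range(3):
            for c in range(3):
                off = (a - 1) * hp * wp + (b - 1) * wp + (c - 1)
                lo = max(0, -off)
                hi = min(n_pad, n_pad - off)
                dw[:, :, a, b, c] += dypf[:, lo:hi] @ xpf[:, lo + off:hi + off].T


def _conv3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3x3 convolution with zero padding 1; returns (y, padded x)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    y = np.empty((w.shape[0],) + x.shape[1:], dtype=x.dtype)
    _conv3_fwd_kernel(xp, w.astype(x.dtype, copy=False), b.astype(x.dtype, copy=False), y)
    return y, xp


class Conv3x3:
    """3x3x3 convolution, stride 1, zero padding 1 (direct numba kernels)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "conv"):
        self.cin, self.cout = cin, cout
        self.w = Param(_he_init(rng, (cout, cin, 3, 3, 3), cin * 27), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._xp: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, self._xp = _conv3(x, self.w.data, self.b.data)
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        dy = np.ascontiguousarray(dy)
        dw = np.zeros(self.w.data.shape, dtype=dy.dtype)
        _conv3_dw(self._xp, dy, dw)
        self.w.grad += dw
        self.b.grad += dy.sum(axis=(1, 2, 3))
        self._xp = None
        if not need_dx:
            return None
        # data gradient = convolution of dy with the flipped, transposed kernel
        wt = np.ascontiguousarray(
            self.w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        )
        dx, _ = _conv3(dy, wt, np.zeros(self.cin, dtype=dy.dtype))
        return dx


class Conv1x1:
    """1x1x1 convolution (pointwise linear map over channels)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "conv1"):
        self.cin, self.cout = cin, cout
        self.w = Param(_he_init(rng, (cout, cin), cin), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.tensordot(self.w.data, x, axes=([1], [0])) + self.b.data[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += np.tensordot(dy, self._x, axes=([1, 2, 3], [1, 2, 3]))
        self.b.grad += dy.sum(axis=(1, 2, 3))
        dx = np.tensordot(self.w.data.T, dy, axes=([1], [0]))
        self._x = None
        return dx


class GroupNorm:
    """Group normalization over channel groups of a (C, D, H, W) tensor."""

    def __init__(self, channels: int, groups: int, name: str = "gn"):
        if channels % groups != 0:
            raise ValueError("channels must be divisible by groups")
        self.c, self.g = channels, groups
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.eps = 1e-5
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        shape = x.shape
        xg = x.reshape(self.g, -1)
        mu = xg.mean(axis=1, keepdims=True)
        m2 = np.einsum("ij,ij->i", xg, xg)[:, None] / xg.shape[1]
        var = np.maximum(m2 - mu * mu, 0.0)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(shape)
        self._cache = (xhat, inv)
        return self.gamma.data[:, None, None, None] * xhat + self.beta.data[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        shape = dy.shape
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = (dy * self.gamma.data[:, None, None, None]).reshape(self.g, -1)
        xh = xhat.reshape(self.g, -1)
        m = dxhat.shape[1]
        dx = inv * (dxhat - dxhat.mean(axis=1, keepdims=True)
                    - xh * (dxhat * xh).mean(axis=1, keepdims=True))
        self._cache = None
        return dx.reshape(shape)


class ReLU:
    """In-place ReLU; the (sparse) output itself encodes the backward mask."""

    def __init__(self):
        self._y = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.maximum(x, 0, out=x)  # x is always layer-owned here
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * (self._y > 0)
        self._y = None
        return dx


class MaxPool2:
    """2x2x2 max pooling, stride 2.  Gradient split equally among ties."""

    def __init__(self):
        self._cache = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        win = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = win.max(axis=(2, 4, 6))
        self._cache = (win, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win, y = self._cache
        mask = win == y[:, :, None, :, None, :, None]
        count = mask.sum(axis=(2, 4, 6), keepdims=True)
        dx = mask * (dy[:, :, None, :, None, :, None] / count)
        c = dx.shape[0]
        self._cache = None
        d2, h2, w2 = dy.shape[1:]
        return dx.reshape(c, d2 * 2, h2 * 2, w2 * 2)


class UpConv2:
    """Transposed convolution, kernel 2, stride 2 (doubles every axis)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "up"):
        self.cin, self.cout = cin, cout
        self.w = Param(_he_init(rng, (cin, cout, 2, 2, 2), cin * 8), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._x = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        d, h, w = x.shape[1:]
        t = np.tensordot(self.w.data, x, axes=([0], [0]))  # (cout,2,2,2,d,h,w)
        t = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(self.cout, 2 * d, 2 * h, 2 * w)
        return t + self.b.data[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d2, h2, w2 = dy.shape[1:]
        dyr = dy.reshape(self.cout, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2)
        dyr = np.ascontiguousarray(dyr.transpose(0, 2, 4, 6, 1, 3, 5))  # (cout,2,2,2,d,h,w)
        self.b.grad += dy.sum(axis=(1, 2, 3))
        self.w.grad += np.tensordot(self._x, dyr, axes=([1, 2, 3], [4, 5, 6]))
        dx = np.tensordot(self.w.data, dyr, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# trilinear x2 upsampling (separable, matrix form so the adjoint is exact)
# ---------------------------------------------------------------------------

def _upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) matrix of 1-D linear x2 upsampling, half-voxel aligned.

    Output sample o maps to input coordinate o/2 - 1/4; border samples clamp
    to the edge value.
    """
    u = np.zeros((2 * n, n), dtype=FLOAT)
    for i in range(n):
        u[2 * i, max(i - 1, 0)] += 0.25
        u[2 * i, i] += 0.75
        u[2 * i + 1, i] += 0.75
        u[2 * i + 1, min(i + 1, n - 1)] += 0.25
    return u


_UP_CACHE: dict[int, np.ndarray] = {}


def _up_mat(n: int) -> np.ndarray:
    if n not in _UP_CACHE:
        _UP_CACHE[n] = _upsample_matrix(n)
    return _UP_CACHE[n]


def upsample2_trilinear(x: np.ndarray) -> np.ndarray:
    """Trilinear x2 upsampling of a (C, D, H, W) tensor along each spatial axis."""
    for axis in (1, 2, 3):
        u = _up_mat(x.shape[axis])
        x = np.moveaxis(np.tensordot(u, x, axes=([1], [axis])), 0, axis)
    return np.ascontiguousarray(x)


def upsample2_trilinear_adjoint(dy: np.ndarray) -> np.ndarray:
    """Exact adjoint (transpose) of :func:`upsample2_trilinear`."""
    for axis in (1, 2, 3):
        u = _up_mat(dy.shape[axis] // 2)
        dy = np.moveaxis(np.tensordot(u.T, dy, axes=([1], [axis])), 0, axis)
    return np.ascontiguousarray(dy)


# ---------------------------------------------------------------------------
# attention gate
# ---------------------------------------------------------------------------

@dataclass
class AttentionGateParams:
    """Weights of one additive attention gate.

    ``w_x``: (F_int, C_x) map on the fine feature map; ``w_g``: (F_int, C_g)
    map on the gating signal; ``psi``: (F_int,) map to the single attention
    channel; ``b_xg``: (F_int,) bias of the additive term; ``b_psi``: scalar
    bias of psi.  All maps are 1x1x1 convolutions.
    """

    w_x: np.ndarray
    w_g: np.ndarray
    psi: np.ndarray
    b_xg: np.ndarray
    b_psi: float

    def __post_init__(self) -> None:
        self.w_x = np.asarray(self.w_x, dtype=FLOAT)
        self.w_g = np.asarray(self.w_g, dtype=FLOAT)
        self.psi = np.asarray(self.psi, dtype=FLOAT).reshape(-1)
        self.b_xg = np.asarray(self.b_xg, dtype=FLOAT).reshape(-1)
        f_int = self.w_x.shape[0]
        if f_int < 1:
            raise ValueError("intermediate channel count must be >= 1")
        if self.w_g.shape[0] != f_int or self.psi.shape[0] != f_int or self.b_xg.shape[0] != f_int:
            raise ValueError("attention-gate parameter shapes disagree on F_int")
        for a in (self.w_x, self.w_g, self.psi, self.b_xg):
            if not np.all(np.isfinite(a)):
                raise ValueError("attention-gate parameters must be finite")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def attention_gate(
    x: np.ndarray, g: np.ndarray, params: AttentionGateParams
) -> tuple[np.ndarray, np.ndarray]:
    """Apply an additive attention gate to a skip feature map.

    ``x`` is the fine-level feature map, shape ``(C_x, D, H, W)``; ``g`` the
    gating signal at the same grid or at the next-coarser grid (every axis
    halved), shape ``(C_g, d, h, w)``.  A coarse ``g`` is first upsampled to
    x's grid by trilinear interpolation.  Returns ``(x * alpha, alpha)``
    with ``alpha = sigmoid(psi(ReLU(W_x x + W_g g + b_xg)) + b_psi)`` in
    [0, 1], broadcast over channels.

    Batched 5-D inputs ``(N, C, D, H, W)`` are accepted and processed per
    sample.
    """
    if x.ndim == 5:
        outs = [attention_gate(xi, gi, params) for xi, gi in zip(x, g)]
        return np.stack([o[0] for o in outs]), np.stack([o[1] for o in outs])
    if x.ndim != 4 or g.ndim != 4:
        raise ValueError("x and g must be (C, D, H, W) tensors")
    if params.w_x.shape[1] != x.shape[0]:
        raise ValueError(f"w_x expects {params.w_x.shape[1]} channels, x has {x.shape[0]}")
    if params.w_g.shape[1] != g.shape[0]:
        raise ValueError(f"w_g expects {params.w_g.shape[1]} channels, g has {g.shape[0]}")
    if g.shape[1:] == x.shape[1:]:
        gu = g
    elif tuple(2 * s for s in g.shape[1:]) == x.shape[1:]:
        gu = upsample2_trilinear(np.asarray(g, dtype=FLOAT))
    else:
        raise ValueError(f"g grid {g.shape[1:]} is neither x's grid {x.shape[1:]} nor its half")
    a = (np.tensordot(params.w_x, x, axes=([1], [0]))
         + np.tensordot(params.w_g, gu, axes=([1], [0]))
         + params.b_xg[:, None, None, None])
    r = np.maximum(a, 0.0)
    q = np.tensordot(params.psi, r, axes=([0], [0])) + params.b_psi
    alpha = _sigmoid(q)
    return x * alpha[None], alpha


class AttentionGateLayer:
    """Trainable attention gate used on each skip connection of the U-Net."""

    def __init__(self, cx: int, cg: int, rng: np.random.Generator, name: str = "ag"):
        f_int = max(cx // 2, 1)
        self.wx = Param(_he_init(rng, (f_int, cx), cx), f"{name}.wx")
        self.wg = Param(_he_init(rng, (f_int, cg), cg), f"{name}.wg")
        self.psi = Param(_he_init(rng, (f_int,), f_int), f"{name}.psi")
        self.bxg = Param(np.zeros(f_int), f"{name}.bxg")
        self.bpsi = Param(np.zeros(1), f"{name}.bpsi")
        self._cache = None
        self.last_alpha: np.ndarray | None = None

    @property
    def params(self):
        return [self.wx, self.wg, self.psi, self.bxg, self.bpsi]

    def forward(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        gu = upsample2_trilinear(g) if g.shape[1:] != x.shape[1:] else g
        a = (np.tensordot(self.wx.data, x, axes=([1], [0]))
             + np.tensordot(self.wg.data, gu, axes=([1], [0]))
             + self.bxg.data[:, None, None, None])
        r = np.maximum(a, 0.0)
        q = np.tensordot(self.psi.data, r, axes=([0], [0])) + self.bpsi.data[0]
        alpha = _sigmoid(q)
        self._cache = (x, gu, a > 0, r, alpha, g.shape)
        self.last_alpha = alpha
        return x * alpha[None]

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, gu, relu_mask, r, alpha, g_shape = self._cache
        dx = dy * alpha[None]
        dalpha = (dy * x).sum(axis=0)
        dq = dalpha * alpha * (1.0 - alpha)
        self.bpsi.grad += dq.sum()
        self.psi.grad += np.tensordot(r, dq, axes=([1, 2, 3], [0, 1, 2]))
        dr = self.psi.data[:, None, None, None] * dq[None]
        da = np.where(relu_mask, dr, FLOAT(0.0))
        self.bxg.grad += da.sum(axis=(1, 2, 3))
        self.wx.grad += np.tensordot(da, x, axes=([1, 2, 3], [1, 2, 3]))
        self.wg.grad += np.tensordot(da, gu, axes=([1, 2, 3], [1, 2, 3]))
        dx += np.tensordot(self.wx.data.T, da, axes=([1], [0]))
        dgu = np.tensordot(self.wg.data.T, da, axes=([1], [0]))
        dg = upsample2_trilinear_adjoint(dgu) if g_shape[1:] != x.shape[1:] else dgu
        self._cache = None
        return dx, dg


# ---------------------------------------------------------------------------
# the U-Net
# ---------------------------------------------------------------------------

class _ConvBlock:
    """conv3 -> [GN] -> ReLU -> conv3 -> [GN] -> ReLU."""

    def __init__(self, cin, cout, gn_groups, use_gn, rng, name):
        self.layers = []
        self.c1 = Conv3x3(cin, cout, rng, f"{name}.c1")
        self.n1 = GroupNorm(cout, gn_groups, f"{name}.n1") if use_gn else None
        self.r1 = ReLU()
        self.c2 = Conv3x3(cout, cout, rng, f"{name}.c2")
        self.n2 = GroupNorm(cout, gn_groups, f"{name}.n2") if use_gn else None
        self.r2 = ReLU()

    @property
    def params(self):
        p = self.c1.params + self.c2.params
        if self.n1 is not None:
            p += self.n1.params + self.n2.params
        return p

    def forward(self, x):
        x = self.c1.forward(x)
        if self.n1 is not None:
            x = self.n1.forward(x)
        x = self.r1.forward(x)
        x = self.c2.forward(x)
        if self.n2 is not None:
            x = self.n2.forward(x)
        return self.r2.forward(x)

    def backward(self, dy, need_dx: bool = True):
        dy = self.r2.backward(dy)
        if self.n2 is not None:
            dy = self.n2.backward(dy)
        dy = self.c2.backward(dy)
        dy = self.r1.backward(dy)
        if self.n1 is not None:
            dy = self.n1.backward(dy)
        return self.c1.backward(dy, need_dx=need_dx)


class SegmentationModel:
    """3D U-Net (optionally attention-gated) mapping a volume to per-voxel
    needle probabilities.

    Input ``(1, D, H, W)`` (or ``(D, H, W)``); each spatial dim must be
    divisible by ``2**(depth-1)``.  Output has the same spatial shape with
    values in (0, 1).
    """

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.depth
        ch = [config.base_channels * 2 ** l for l in range(d)]
        self.channels = ch
        gn_dec = not config.gn_encoder_only
        self.enc = [
            _ConvBlock(config.in_channels if l == 0 else ch[l - 1], ch[l],
                       config.gn_groups, True, rng, f"enc{l}")
            for l in range(d)
        ]
        self.pools = [MaxPool2() for _ in range(d - 1)]
        self.ups = [UpConv2(ch[l + 1], ch[l], rng, f"up{l}") for l in range(d - 1)]
        self.up_relus = [ReLU() for _ in range(d - 1)]
        self.dec = [
            _ConvBlock(2 * ch[l], ch[l], config.gn_groups, gn_dec, rng, f"dec{l}")
            for l in range(d - 1)
        ]
        self.gates = (
            [AttentionGateLayer(ch[l], ch[l + 1], rng, f"ag{l}") for l in range(d - 1)]
            if config.use_attention else None
        )
        self.head = Conv1x1(ch[0], config.out_channels, rng, "head")
        # background-prior initialization: needles occupy ~1e-3 of the volume,
        # so starting the sigmoid near zero keeps the soft-Dice denominator
        # small and the early gradient signal on the foreground strong
        self.head.b.data[:] = -4.0
        self._cache = None

    # -- parameter plumbing ------------------------------------------------
    @property
    def params(self) -> list[Param]:
        p = []
        for b in self.enc:
            p += b.params
        for u in self.ups:
            p += u.params
        for b in self.dec:
            p += b.params
        if self.gates is not None:
            for gate in self.gates:
                p += gate.params
        p += self.head.params
        return p

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def n_attention_gates(self) -> int:
        return 0 if self.gates is None else len(self.gates)

    # -- forward / backward ------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4:
            raise ValueError("input must be (C, D, H, W) or (D, H, W)")
        div = 2 ** (self.config.depth - 1)
        for s in x.shape[1:]:
            if s % div != 0:
                raise ValueError(
                    f"spatial dims {x.shape[1:]} must be divisible by {div} "
                    f"(depth {self.config.depth})"
                )
        return np.ascontiguousarray(x, dtype=FLOAT)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._check_shape(x)
        d = self.config.depth
        skips = []
        h = x
        for l in range(d - 1):
            h = self.enc[l].forward(h)
            skips.append(h)
            h = self.pools[l].forward(h)
        h = self.enc[d - 1].forward(h)
        for l in range(d - 2, -1, -1):
            g = h  # coarse gating signal for this level's attention gate
            u = self.up_relus[l].forward(self.ups[l].forward(h))
            skip = self.gates[l].forward(skips[l], g) if self.gates is not None else skips[l]
            h = self.dec[l].forward(np.concatenate([skip, u], axis=0))
        logits = self.head.forward(h)
        prob = _sigmoid(logits)
        self._cache = prob
        return prob

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients of a scalar loss given dL/dprob."""
        prob = self._cache
        dy = dprob * prob * (1.0 - prob)
        dy = self.head.backward(dy)
        d = self.config.depth
        dskips = [None] * (d - 1)
        for l in range(0, d - 1):
            c = self.channels[l]
            dcat = self.dec[l].backward(dy)
            dskip, du = dcat[:c], dcat[c:]
            dg_extra = None
            if self.gates is not None:
                dskip, dg_extra = self.gates[l].backward(dskip)
            dskips[l] = dskip
            dy = self.ups[l].backward(self.up_relus[l].backward(du))
            if dg_extra is not None:
                dy = dy + dg_extra
        dy = self.enc[d - 1].backward(dy)
        for l in range(d - 2, -1, -1):
            dy = self.pools[l].backward(dy)
            dy = dy + dskips[l]
            dy = self.enc[l].backward(dy, need_dx=(l > 0))
        self._cache = None

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params:
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name}")
            if state[p.name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data[...] = state[p.name]

    def save(self, path) -> None:
        """Save weights (.npz) with a sidecar JSON of the topology config."""
        import pathlib

        path = pathlib.Path(path)
        np.savez(path, **self.state_dict())
        path.with_suffix(".json").write_text(self.config.to_json())

    @classmethod
    def load(cls, path, seed: int = 0) -> "SegmentationModel":
        import pathlib

        path = pathlib.Path(path)
        config = NetConfig.from_json(path.with_suffix(".json").read_text())
        model = cls(config, seed=seed)
        with np.load(path) as f:
            model.load_state_dict({k: f[k] for k in f.files})
        return model


def build_model(config: NetConfig, seed: int = 0) -> SegmentationModel:
    """Construct a (seeded) segmentation network from its topology config."""
    return SegmentationModel(config, seed=seed)


# ---------------------------------------------------------------------------
# soft Dice loss
# ---------------------------------------------------------------------------

def soft_dice_loss(
    pred: np.ndarray, target: np.ndarray, cfg: LossConfig | None = None
) -> tuple[float, np.ndarray]:
    """Soft Dice loss ``1 - 2 sum(p*t) / (sum(p) + sum(t) + eps)``.

    ``pred`` holds probabilities in [0, 1]; ``target`` is a binary mask of
    the same shape.  Returns ``(loss, dloss_dpred)`` so the gradient can be
    fed straight into :meth:`SegmentationModel.backward`.
    """
    cfg = cfg or LossConfig()
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    t = target.astype(pred.dtype)
    inter = float((pred * t).sum())
    denom = float(pred.sum()) + float(t.sum()) + cfg.epsilon
    loss = 1.0 - 2.0 * inter / denom
    # d/dp [ -2 (p.t) / (sum p + sum t + eps) ]
    grad = (-2.0 * t / denom + 2.0 * inter / denom ** 2).astype(pred.dtype)
    return loss, grad


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
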