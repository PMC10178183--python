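"""Minimal CNN engine for the dual-input U-Net.

Implements exactly the layers the segmenter needs — 3x3 "same" convolution,
ReLU, 2x2 max-pooling, nearest-neighbour 2x upsampling, channel
concatenation, a 1x1 output convolution with sigmoid — together with
hand-derived backpropagation and an Adam optimizer.

Tensors are channels-first float32 ``(batch, channels, height, width)``.
The convolution inner loops run over the contiguous width axis and are
compiled with numba, which keeps them SIMD-vectorized while touching each
array exactly once; this outperforms an im2col/GEMM formulation here because
the channel counts are small and the patch matrices would dominate memory
traffic.  The input gradient of a convolution is itself a convolution of the
output gradient with the spatially flipped, channel-transposed kernel, so
the same kernel serves forward and backward.

Everything is deterministic for a fixed seed on a given machine: single
threaded, fixed reduction order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32


# ------------------------------------------------------------ numba kernels

@njit(fastmath=True, cache=True)
def _conv3x3_kernel(xp, w, b, out, relu):
    """xp (B,Ci,H+2,W+2) zero-padded, w (Co,Ci,3,3), b (Co,), out (B,Co,H,W)."""
    B, Ci, Hp, Wp = xp.shape
    Co = w.shape[0]
    H, W = Hp - 2, Wp - 2
    for bi in range(B):
        for co in range(Co):
            for i in range(H):
                for j in range(W):
                    out[bi, co, i, j] = b[co]
                for ci in range(Ci):
                    for dy in range(3):
                        for dx in range(3):
                            wv = w[co, ci, dy, dx]
                            for j in range(W):
                                out[bi, co, i, j] += wv * xp[bi, ci, i + dy, j + dx]
                if relu:
                    for j2 in range(W):
                        if out[bi, co, i, j2] < 0.0:
                            out[bi, co, i, j2] = 0.0


@njit(fastmath=True, cache=True)
def _conv3x3_dw_kernel(xp, g, dw, db):
    """dw[co,ci,dy,dx] = sum_{b,i,j} g[b,co,i,j] * xp[b,ci,i+dy,j+dx];
    db[co] accumulates the plain sum of g."""
    B, Ci, Hp, Wp = xp.shape
    Co = g.shape[1]
    H, W = Hp - 2, Wp - 2
    for bi in range(B):
        for co in range(Co):
            sb = F32(0.0)
            for i in range(H):
                for j in range(W):
                    sb += g[bi, co, i, j]
            db[co] += sb
            for ci in range(Ci):
                for dy in range(3):
                    for dx in range(3):
                        acc = F32(0.0)
                        for i in range(H):
                            for j in range(W):
                                acc += g[bi, co, i, j] * xp[bi, ci, i + dy, j + dx]
                        dw[co, ci, dy, dx] += acc


@njit(fastmath=True, cache=True)
def _maxpool2_kernel(x, out, idx):
    """2x2 max pooling; idx records the winning position (0..3, first on
    ties) for exact gradient routing."""
    B, C, H, W = x.shape
    for bi in range(B):
        for c in range(C):
            for i in range(H // 2):
                for j in range(W // 2):
                    i0, j0 = 2 * i, 2 * j
                    best = x[bi, c, i0, j0]
                    k = 0
                    if x[bi, c, i0, j0 + 1] > best:
                        best = x[bi, c, i0, j0 + 1]
                        k = 1
                    if x[bi, c, i0 + 1, j0] > best:
                        best = x[bi, c, i0 + 1, j0]
                        k = 2
                    if x[bi, c, i0 + 1, j0 + 1] > best:
                        best = x[bi, c, i0 + 1, j0 + 1]
                        k = 3
                    out[bi, c, i, j] = best
                    idx[bi, c, i, j] = k


@njit(fastmath=True, cache=True)
def _maxpool2_bwd_kernel(idx, g, dx):
    B, C, H2, W2 = g.shape
    for bi in range(B):
        for c in range(C):
            for i in range(H2):
                for j in range(W2):
                    k = idx[bi, c, i, j]
                    dx[bi, c, 2 * i + k // 2, 2 * j + k % 2] = g[bi, c, i, j]


def _pad_hw(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, relu: bool = False):
    """Returns (out, xp); xp (the padded input) is reused by the backward
    pass for the weight gradient."""
    xp = _pad_hw(np.ascontiguousarray(x))
    B, _, Hp, Wp = xp.shape
    out = np.empty((B, w.shape[0], Hp - 2, Wp - 2), F32)
    _conv3x3_kernel(xp, w, b, out, relu)
    return out, xp


def conv3x3_backward(xp: np.ndarray, w: np.ndarray, dy_out: np.ndarray):
    """Returns (dx, dw, db) given the forward's padded input."""
    g = np.ascontiguousarray(dy_out)
    dw = np.zeros_like(w)
    db = np.zeros(w.shape[0], w.dtype)
    _conv3x3_dw_kernel(xp, g, dw, db)
    # dX = conv(g, kernel flipped spatially, channels transposed)
    wt = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    gp = _pad_hw(g)
    dx = np.empty((g.shape[0], w.shape[1], g.shape[2], g.shape[3]), F32)
    _conv3x3_kernel(gp, wt, np.zeros(w.shape[1], F32), dx, False)
    return dx, dw, db


def conv1x1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """w (Ci,Co): pointwise convolution."""
    out = np.tensordot(w.T, x, axes=([1], [1]))  # (Co,B,H,W)
    out = out.transpose(1, 0, 2, 3) + b[None, :, None, None]
    return np.ascontiguousarray(out.astype(F32, copy=False))


def conv1x1_backward(x: np.ndarray, w: np.ndarray, dy_out: np.ndarray):
    dw = np.tensordot(x, dy_out, axes=([0, 2, 3], [0, 2, 3]))  # (Ci,Co)
    db = dy_out.sum(axis=(0, 2, 3))
    dx = np.tensordot(dy_out, w.T, axes=([1], [0])).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx.astype(F32, copy=False)), dw, db


def maxpool2_forward(x: np.ndarray):
    """Returns (pooled, winner_index); ties route to the first window slot."""
    B, C, H, W = x.shape
    x = np.ascontiguousarray(x)
    out = np.empty((B, C, H // 2, W // 2), x.dtype)
    idx = np.empty(out.shape, np.uint8)
    _maxpool2_kernel(x, out, idx)
    return out, idx


def maxpool2_backward(idx: np.ndarray, dy_out: np.ndarray) -> np.ndarray:
    B, C, H2, W2 = dy_out.shape
    dx = np.zeros((B, C, H2 * 2, W2 * 2), dy_out.dtype)
    _maxpool2_bwd_kernel(idx, np.ascontiguousarray(dy_out), dx)
    return dx


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy_out: np.ndarray) -> np.ndarray:
    B, C, H, W = dy_out.shape
    return dy_out.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)).astype(F32, copy=False)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# -------------------------------------------------------------- dice loss

def batch_dice_loss_and_grad(prob: np.ndarray, target: np.ndarray, smooth: float):
    """Mean per-sample soft dice loss over the batch and dL/dprob.

    prob, target: (B,H,W) in [0,1].
    """
    B = prob.shape[0]
    p = prob.reshape(B, -1)
    t = target.reshape(B, -1)
    inter = (p * t).sum(axis=1)
    num = 2.0 * inter + smooth
    den = p.sum(axis=1) + t.sum(axis=1) + smooth
    loss = float(np.mean(1.0 - num / den))
    dp = -(2.0 * t * den[:, None] - num[:, None]) / (den[:, None] ** 2) / B
    return loss, dp.reshape(prob.shape).astype(F32)


# ------------------------------------------------------------------ U-Net

#: conv blocks per encoder level for the 13-conv VGG16 layout
_VGG16_CONVS = (2, 2, 3, 3, 3)
_VGG16_WIDTHS = (64, 128, 256, 512, 512)


class NumpyUNet:
    """Encoder-decoder segmentation network with skip connections.

    ``encoder_kind="small"`` uses `depth` resolution levels of width
    ``base_channels * 2**level`` with two 3x3 convs per encoder level; each
    decoder level upsamples (nearest, 2x), concatenates the skip tensor and
    applies one 3x3 conv.  ``encoder_kind="vgg16_style"`` reproduces the
    13-convolution VGG16 channel layout (64..512, 5 levels) with a two-conv
    decoder.  The final layer is a 1x1 convolution with a per-pixel sigmoid.

    Inputs whose height/width are not divisible by ``2**(depth-1)`` are
    zero-padded on the bottom/right for the forward pass and the output is
    cropped back; the applied padding is recorded in :attr:`last_padding`.
    """

    def __init__(self, in_channels: int, depth: int, base_channels: int,
                 encoder_kind: str = "small",
                 pretrained_adaptation: str = "random",
                 rng: np.random.Generator | None = None):
        if encoder_kind not in ("small", "vgg16_style"):
            raise ValueError(f"unknown encoder_kind {encoder_kind!r}")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.encoder_kind = encoder_kind
        if encoder_kind == "vgg16_style":
            self.depth = len(_VGG16_WIDTHS)
            self.widths = list(_VGG16_WIDTHS)
            self.enc_convs = list(_VGG16_CONVS)
            self.dec_convs = 2
        else:
            self.depth = depth
            self.widths = [base_channels * 2 ** i for i in range(depth)]
            self.enc_convs = [2] * depth
            self.dec_convs = 1
        self.params: dict[str, np.ndarray] = {}
        self.last_padding: tuple[int, int] = (0, 0)
        self._build(rng, pretrained_adaptation)

    # -- construction -----------------------------------------------------

    def _he_conv(self, rng, ci, co):
        std = np.sqrt(2.0 / (9 * ci))
        return rng.normal(0.0, std, size=(co, ci, 3, 3)).astype(F32)

    def _build(self, rng, pretrained_adaptation):
        p = self.params
        ci = self.in_channels
        for lvl, width in enumerate(self.widths):
            for j in range(self.enc_convs[lvl]):
                if lvl == 0 and j == 0 and ci == 6 and pretrained_adaptation == "replicate_halve":
                    # adapt a 3-channel stem to 6 channels: replicate the
                    # kernels across the extra channels and halve, preserving
                    # the expected activation magnitude
                    w3 = self._he_conv(rng, 3, width)
                    w = np.concatenate([w3, w3], axis=1) * F32(0.5)
                else:
                    w = self._he_conv(rng, ci, width)
                p[f"enc{lvl}_{j}_w"] = w
                p[f"enc{lvl}_{j}_b"] = np.zeros(width, F32)
                ci = width
        for lvl in range(self.depth - 2, -1, -1):
            w_hi, w_lo = self.widths[lvl + 1], self.widths[lvl]
            ci = w_lo + w_hi  # skip + upsampled channels
            for j in range(self.dec_convs):
                p[f"dec{lvl}_{j}_w"] = self._he_conv(rng, ci, w_lo)
                p[f"dec{lvl}_{j}_b"] = np.zeros(w_lo, F32)
                ci = w_lo
        std = np.sqrt(2.0 / self.widths[0])
        p["out_w"] = rng.normal(0.0, std, size=(self.widths[0], 1)).astype(F32)
        p["out_b"] = np.zeros(1, F32)

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward / backward ----------------------------------------------

    def _pad_input(self, x):
        m = 2 ** (self.depth - 1)
        B, C, H, W = x.shape
        ph = (-H) % m
        pw = (-W) % m
        self.last_padding = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x (B,Cin,H,W) float32 -> per-pixel probability (B,H,W)."""
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"model expects {self.in_channels} input channels, got {x.shape[1]}"
            )
        H0, W0 = x.shape[2], x.shape[3]
        x = self._pad_input(x.astype(F32, copy=False))
        p = self.params
        cache: dict | None = {} if keep_cache else None

        def conv_relu(h, name):
            out, xp = conv3x3_forward(h, p[f"{name}_w"], p[f"{name}_b"], relu=True)
            if keep_cache:
                cache[f"{name}_xp"] = xp
                cache[f"{name}_out"] = out
            return out

        h = x
        skips = []
        for lvl in range(self.depth):
            for j in range(self.enc_convs[lvl]):
                h = conv_relu(h, f"enc{lvl}_{j}")
            if lvl < self.depth - 1:
                skips.append(h)
                h, idx = maxpool2_forward(h)
                if keep_cache:
                    cache[f"pool{lvl}_idx"] = idx
        for lvl in range(self.depth - 2, -1, -1):
            h = np.concatenate([skips[lvl], upsample2_forward(h)], axis=1)
            for j in range(self.dec_convs):
                h = conv_relu(h, f"dec{lvl}_{j}")
        logit = conv1x1_forward(h, p["out_w"], p["out_b"])
        prob = sigmoid(logit)[:, 0]
        if keep_cache:
            cache["out_in"] = h
            cache["prob"] = prob
            return prob[:, :H0, :W0], cache
        return prob[:, :H0, :W0]

    def backward(self, cache: dict, dprob: np.ndarray) -> dict[str, np.ndarray]:
        """dprob (B,H,W) = dL/dprob on the *unpadded* output."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        prob = cache["prob"]
        if dprob.shape != prob.shape:
            full = np.zeros_like(prob)
            full[:, : dprob.shape[1], : dprob.shape[2]] = dprob
            dprob = full
        dlogit = (dprob * prob * (1.0 - prob))[:, None].astype(F32)
        dh, grads["out_w"], grads["out_b"] = conv1x1_backward(
            cache["out_in"], p["out_w"], dlogit
        )

        def conv_relu_bwd(dh, name):
            dh = dh * (cache[f"{name}_out"] > 0)
            dh, grads[f"{name}_w"], grads[f"{name}_b"] = conv3x3_backward(
                cache[f"{name}_xp"], p[f"{name}_w"], dh
            )
            return dh

        dskips = {}
        # decoder levels ran depth-2 .. 0 in forward, so unwind 0 .. depth-2
        for lvl in range(self.depth - 1):
            for j in range(self.dec_convs - 1, -1, -1):
                dh = conv_relu_bwd(dh, f"dec{lvl}_{j}")
            w_lo = self.widths[lvl]
            dskips[lvl] = dh[:, :w_lo]
            dh = upsample2_backward(np.ascontiguousarray(dh[:, w_lo:]))
        for lvl in range(self.depth - 1, -1, -1):
            if lvl < self.depth - 1:
                dh = maxpool2_backward(cache[f"pool{lvl}_idx"], dh)
                dh = dh + dskips[lvl]
            for j in range(self.enc_convs[lvl] - 1, -1, -1):
                dh = conv_relu_bwd(dh, f"enc{lvl}_{j}")
        return grads


class Adam:
    """Adam optimizer over a NumpyUNet's parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            self.params[k] -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)
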