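"""The counting network: backbone, super-token attention, channel attention,
feature fusion and point-proposal heads.

The model follows the point-proposal counting paradigm: a convolutional
backbone produces multi-scale feature maps; the deepest map is globally
contextualised by a super-token attention block; an FPN-style merge yields a
single fused map at stride 8; efficient channel attention re-weights its
channels; and two small convolutional heads regress per-reference-point
offsets and confidence logits.  A fixed grid of reference points (several
per fused-map cell) plus the regressed offsets gives the predicted point
set; the count is the number of confident predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import (Conv2d, BatchNorm2d, DepthwiseConv2d, Linear, Module,
                       ModuleList, Tensor)
from .point_core import PointSet

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class EcaConfig:
    gamma: float = 2.0
    b: float = 1.0
    kernel_override: int | None = None


@dataclass
class SvitConfig:
    grid: tuple = (8, 8)
    assoc_iters: int = 1
    heads: int = 2
    ffn_expansion: int = 2


@dataclass
class NetworkConfig:
    backbone: str = "tiny"  # {"vgg19_bn", "vgg16", "tiny"}
    fpn_channels: int = 64
    points_per_cell: int = 4
    head_depth: int = 2
    confidence_threshold: float = 0.5
    svit: SvitConfig = field(default_factory=SvitConfig)
    svit_enabled: bool = True
    eca: EcaConfig = field(default_factory=EcaConfig)
    eca_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.confidence_threshold < 1.0):
            raise ValueError("confidence_threshold must be in (0, 1)")
        if self.points_per_cell < 1:
            raise ValueError("points_per_cell must be >= 1")


@dataclass
class ProposalSet:
    """Per-reference-point predictions for one image."""

    reference_points: PointSet
    offsets: np.ndarray  # (N, 2) pixels
    scores: np.ndarray  # (N,) in (0, 1)

    def __post_init__(self):
        if not (len(self.reference_points) == len(self.offsets) == len(self.scores)):
            raise ValueError("reference/offset/score lengths must agree")

    @property
    def predicted_points(self) -> np.ndarray:
        return self.reference_points.points + self.offsets


def decode_points(proposals: ProposalSet, tau: float) -> PointSet:
    """Confident predictions: reference + offset where score >= tau."""
    if not (0.0 < tau < 1.0) and tau != 1.0:
        raise ValueError("tau must be in (0, 1]")
    keep = proposals.scores >= tau
    return PointSet(proposals.predicted_points[keep])


# ---------------------------------------------------------------------------
# Efficient channel attention
# ---------------------------------------------------------------------------

def eca_kernel_size(C: int, cfg: EcaConfig | None = None) -> int:
    """Adaptive 1-D kernel width k = odd(|log2(C)/gamma + b/gamma|).

    odd(t): truncate t to an integer, add one if even, floor at 1.
    """
    cfg = cfg or EcaConfig()
    if C < 1:
        raise ValueError("channel count must be >= 1")
    if cfg.kernel_override is not None:
        k = int(cfg.kernel_override)
        if k < 1 or k % 2 == 0:
            raise ValueError("kernel_override must be odd and >= 1")
        return k
    t = abs(math.log2(C) / cfg.gamma + cfg.b / cfg.gamma)
    k = int(t)
    if k % 2 == 0:
        k += 1
    return max(k, 1)


class EcaLayer(Module):
    """Channel gate: global average pool -> 1-D conv across channels ->
    logistic -> channel-wise rescale.  Shape preserving."""

    def __init__(self, channels: int, cfg: EcaConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or EcaConfig()
        rng = rng or np.random.default_rng(0)
        k = eca_kernel_size(channels, cfg)
        self.kernel_size = k
        w = rng.normal(0.0, 1.0 / math.sqrt(k), size=k).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)

    def __call__(self, x):
        desc = ad.global_avg_pool(x)  # (N, C)
        gate = ad.sigmoid(ad.conv1d_channels(desc, self.weight))  # (N, C)
        g4 = ad.reshape(gate, (gate.shape[0], gate.shape[1], 1, 1))
        return x * g4


def eca_apply(fmap, channels: int | None = None, cfg: EcaConfig | None = None, rng=None):
    """Functional form: apply a freshly initialised ECA layer to a map."""
    x = ad.astensor(fmap)
    layer = EcaLayer(x.shape[1] if channels is None else channels, cfg, rng)
    return layer(x)


# ---------------------------------------------------------------------------
# Super-token attention block (CPE -> STA -> ConvFFN)
# ---------------------------------------------------------------------------

class Cpe(Module):
    """Convolutional position embedding: residual depthwise 3x3."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.dw = DepthwiseConv2d(channels, 3, rng=rng)

    def __call__(self, x):
        return x + self.dw(x)


class ConvFfn(Module):
    """Pointwise expand -> depthwise 3x3 -> pointwise project, residual."""

    def __init__(self, channels: int, expansion: int = 2, rng=None):
        super().__init__()
        hidden = channels * expansion
        self.expand = Conv2d(channels, hidden, k=1, rng=rng)
        self.dw = DepthwiseConv2d(hidden, 3, rng=rng)
        self.project = Conv2d(hidden, channels, k=1, rng=rng)

    def __call__(self, x):
        h = ad.relu(self.expand(x))
        h = ad.relu(self.dw(h))
        return x + self.project(h)


def _grid_assignment(H: int, W: int, grid: tuple):
    """Cell index per token, initial mean-pool matrix and the 3x3-neighbor
    mask between tokens and super-token cells."""
    gh, gw = grid
    if gh > H or gw > W:
        raise ValueError(f"super-token grid {grid} larger than map {(H, W)}")
    row_cell = np.minimum((np.arange(H) * gh) // H, gh - 1)
    col_cell = np.minimum((np.arange(W) * gw) // W, gw - 1)
    cell = row_cell[:, None] * gw + col_cell[None, :]  # (H, W)
    cell = cell.reshape(-1)
    M = gh * gw
    init = np.zeros((M, H * W), dtype=np.float32)
    init[cell, np.arange(H * W)] = 1.0
    init /= init.sum(axis=1, keepdims=True)
    # 3x3 neighborhood of each token's own cell
    tok_r, tok_c = cell // gw, cell % gw
    cel_r, cel_c = np.arange(M) // gw, np.arange(M) % gw
    near = (np.abs(tok_r[:, None] - cel_r[None, :]) <= 1) & (
        np.abs(tok_c[:, None] - cel_c[None, :]) <= 1
    )
    return init, near


class SuperTokenAttention(Module):
    """Sparse token/super-token association + self-attention among super
    tokens, broadcast back through the association weights (residual)."""

    def __init__(self, channels: int, cfg: SvitConfig, rng=None):
        super().__init__()
        if channels % cfg.heads:
            raise ValueError("channels must divide attention heads")
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        self.qkv = Linear(channels, 3 * channels, rng=rng)
        self.proj = Linear(channels, channels, rng=rng, init_scale=0.1)
        self.channels = channels
        self._assoc_cache = {}

    def association(self, x):
        """Return (A, S): row-stochastic token->super-token weights over the
        3x3 cell neighborhood and the final super tokens, as Tensors."""
        N, C, H, W = x.shape
        key = (H, W, self.cfg.grid)
        if key not in self._assoc_cache:
            self._assoc_cache[key] = _grid_assignment(H, W, self.cfg.grid)
        init, near = self._assoc_cache[key]
        X = ad.reshape(ad.transpose(x, (0, 2, 3, 1)), (N, H * W, C))
        S = ad.matmul(Tensor(init[None].astype(x.dtype.type)), X)  # (N, M, C)
        neg = np.where(near, 0.0, -1e9).astype(np.float32)[None]
        scale = 1.0 / math.sqrt(C)
        A = None
        for _ in range(max(1, self.cfg.assoc_iters)):
            logits = ad.matmul(X, ad.transpose(S, (0, 2, 1))) * scale + Tensor(neg)
            A = ad.softmax(logits, axis=-1)  # (N, HW, M) row-stochastic
            colsum = ad.tsum(A, axis=1)  # (N, M)
            S = ad.matmul(ad.transpose(A, (0, 2, 1)), X) * ad.reshape(
                ad.power(colsum + 1e-12, -1.0), (N, -1, 1)
            )
        return A, S, X

    def __call__(self, x):
        N, C, H, W = x.shape
        A, S, _ = self.association(x)
        M = S.shape[1]
        h = self.cfg.heads
        dh = C // h
        qkv = self.qkv(S)  # (N, M, 3C)
        qkv = ad.transpose(ad.reshape(qkv, (N, M, 3, h, dh)), (2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]  # (N, h, M, dh)
        attn = ad.softmax(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * (1.0 / math.sqrt(dh)), axis=-1)
        out = ad.matmul(attn, v)  # (N, h, M, dh)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (N, M, C))
        out = self.proj(out)
        up = ad.matmul(A, out)  # (N, HW, C) broadcast back to tokens
        up = ad.transpose(ad.reshape(up, (N, H, W, C)), (0, 3, 1, 2))
        return x + up


def super_token_attention(fmap, cfg: SvitConfig, rng=None):
    """Functional form over a freshly initialised block."""
    x = ad.astensor(fmap)
    return SuperTokenAttention(x.shape[1], cfg, rng)(x)


def cpe_apply(fmap, rng=None):
    x = ad.astensor(fmap)
    return Cpe(x.shape[1], rng)(x)


def conv_ffn(fmap, expansion: int = 2, rng=None):
    x = ad.astensor(fmap)
    return ConvFfn(x.shape[1], expansion, rng)(x)


class SvitBlock(Module):
    """CPE -> super-token attention -> ConvFFN, all shape preserving."""

    def __init__(self, channels: int, cfg: SvitConfig, rng=None):
        super().__init__()
        self.cpe = Cpe(channels, rng)
        self.sta = SuperTokenAttention(channels, cfg, rng)
        self.ffn = ConvFfn(channels, cfg.ffn_expansion, rng)

    def __call__(self, x):
        return self.ffn(self.sta(self.cpe(x)))


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

_VGG_CFG = {
    # conv channel plan; "M" = 2x2 max pool; (ch, s) = strided conv.
    # BN follows every conv.
    "vgg16": [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512],
    "vgg19_bn": [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
                 512, 512, 512, 512, "M", 512, 512, 512, 512],
    # stride-2 stem keeps the test-time config cheap on one CPU
    "tiny": [(16, 2), "M", 32, "M", 48, "M", 64],
}


class Backbone(Module):
    """Conv backbone with taps at stride 8 and stride 16."""

    def __init__(self, variant: str, rng=None):
        super().__init__()
        if variant not in _VGG_CFG:
            raise ValueError(f"unknown backbone '{variant}'")
        rng = rng or np.random.default_rng(0)
        self.variant = variant
        plan = _VGG_CFG[variant]
        self.convs = ModuleList()
        self.bns = ModuleList()
        self._ops = []  # ("conv", idx) or ("pool",)
        cin = 3
        stride = 1
        tap_channels = {}
        for item in plan:
            if item == "M":
                tap_channels.setdefault(stride, cin)
                self._ops.append(("pool",))
                stride *= 2
            else:
                ch, s = item if isinstance(item, tuple) else (item, 1)
                self.convs.append(Conv2d(cin, ch, k=3, stride=s, rng=rng))
                self.bns.append(BatchNorm2d(ch))
                self._ops.append(("conv", len(self.convs) - 1))
                cin = ch
                stride *= s
        # final pool so the deep tap sits at stride 16
        self._ops.append(("pool",))
        tap_channels.setdefault(stride, cin)
        self.total_stride = 16
        self.tap8_channels = tap_channels[8]
        self.tap16_channels = tap_channels[16]

    def __call__(self, x):
        x = ad.astensor(x)
        if x.shape[2] % self.total_stride or x.shape[3] % self.total_stride:
            raise ValueError(
                f"input size {x.shape[2:]} not divisible by stride {self.total_stride}"
            )
        taps = {}
        stride = 1
        for op in self._ops:
            if op[0] == "pool":
                taps.setdefault(stride, x)
                x = ad.maxpool2d(x, 2)
                stride *= 2
            else:
                i = op[1]
                x = ad.relu(self.bns[i](self.convs[i](x)))
                stride *= self.convs[i].stride
        taps.setdefault(stride, x)
        return [taps[8], taps[16]]


def backbone_forward(image, variant: str = "tiny", rng=None):
    """Functional multi-scale forward of a fresh backbone (eval mode)."""
    bb = Backbone(variant, rng).eval()
    return bb(image)


# ---------------------------------------------------------------------------
# Feature fusion (single-merge FPN at stride 8)
# ---------------------------------------------------------------------------

class Fpn(Module):
    def __init__(self, in_channels: list, out_channels: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = list(in_channels)
        self.laterals = ModuleList(
            [Conv2d(c, out_channels, k=1, rng=rng) for c in in_channels]
        )
        self.smooth = Conv2d(out_channels, out_channels, k=3, rng=rng)

    def __call__(self, maps):
        if len(maps) != len(self.laterals):
            raise ValueError("number of maps does not match fusion laterals")
        for m, c in zip(maps, self.in_channels):
            if m.shape[1] != c:
                raise ValueError(f"fusion channel mismatch: got {m.shape[1]}, expected {c}")
        lat = [l(m) for l, m in zip(self.laterals, maps)]
        x = lat[-1]
        for fine in reversed(lat[:-1]):
            factor = fine.shape[2] // x.shape[2]
            x = fine + ad.upsample_nearest(x, factor)
        return self.smooth(x)


def fuse_features(maps, fpn_channels: int = 64, rng=None):
    maps = [ad.astensor(m) for m in maps]
    return Fpn([m.shape[1] for m in maps], fpn_channels, rng)(maps)


# ---------------------------------------------------------------------------
# Proposal heads and the full network
# ---------------------------------------------------------------------------

def reference_pattern(points_per_cell: int) -> np.ndarray:
    """Fixed sub-cell pattern of reference points in cell-fraction units."""
    k = points_per_cell
    side = int(math.ceil(math.sqrt(k)))
    xs = (np.arange(side) + 0.5) / side
    grid = np.stack(np.meshgrid(xs, xs, indexing="xy"), axis=-1).reshape(-1, 2)
    return grid[:k] - 0.5  # centered offsets in [-0.5, 0.5)


def reference_grid(Hf: int, Wf: int, stride: int, points_per_cell: int) -> np.ndarray:
    """Reference points in input-image pixel coordinates, (Hf*Wf*K, 2)."""
    pat = reference_pattern(points_per_cell) * stride
    cy, cx = np.meshgrid(np.arange(Hf), np.arange(Wf), indexing="ij")
    centers = np.stack([(cx + 0.5) * stride, (cy + 0.5) * stride], axis=-1)  # (Hf,Wf,2)
    pts = centers[:, :, None, :] + pat[None, None, :, :]
    return pts.reshape(-1, 2)


class Head(Module):
    def __init__(self, channels: int, out_channels: int, depth: int, rng=None,
                 final_bias: float = 0.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.convs = ModuleList(
            [Conv2d(channels, channels, k=3, rng=rng) for _ in range(max(0, depth - 1))]
        )
        self.final = Conv2d(channels, out_channels, k=3, rng=rng, init_scale=0.01)
        self.final.bias.data[:] = final_bias

    def __call__(self, x):
        for c in self.convs:
            x = ad.relu(c(x))
        return self.final(x)


class CountingNetwork(Module):
    """Backbone -> SViT (deepest map) -> FPN fusion -> ECA -> point heads."""

    STRIDE = 8

    def __init__(self, cfg: NetworkConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg.backbone, rng)
        deep_c = self.backbone.tap16_channels
        if cfg.svit_enabled:
            self.svit = SvitBlock(deep_c, cfg.svit, rng)
        self.fpn = Fpn([self.backbone.tap8_channels, deep_c], cfg.fpn_channels, rng)
        if cfg.eca_enabled:
            self.eca = EcaLayer(cfg.fpn_channels, cfg.eca, rng)
        K = cfg.points_per_cell
        self.reg_head = Head(cfg.fpn_channels, 2 * K, cfg.head_depth, rng)
        # negative prior bias: start with few confident proposals
        self.cls_head = Head(cfg.fpn_channels, K, cfg.head_depth, rng, final_bias=-2.0)

    def __call__(self, x):
        """x: (N,3,H,W) normalized. Returns (offsets_px (N,P,2), logits (N,P))."""
        maps = self.backbone(x)
        if self.cfg.svit_enabled:
            maps[1] = self.svit(maps[1])
        fused = self.fpn(maps)
        if self.cfg.eca_enabled:
            fused = self.eca(fused)
        N, _, Hf, Wf = fused.shape
        K = self.cfg.points_per_cell
        reg = self.reg_head(fused)  # (N, 2K, Hf, Wf)
        cls = self.cls_head(fused)  # (N, K, Hf, Wf)
        reg = ad.reshape(ad.transpose(reg, (0, 2, 3, 1)), (N, Hf * Wf * K, 2))
        logits = ad.reshape(ad.transpose(cls, (0, 2, 3, 1)), (N, Hf * Wf * K))
        offsets = reg * float(self.STRIDE)
        return offsets, logits

    def fused_grid(self, H: int, W: int) -> np.ndarray:
        return reference_grid(H // self.STRIDE, W // self.STRIDE, self.STRIDE,
                              self.cfg.points_per_cell)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """uint8 HWC RGB -> float32 CHW standardized."""
    x = image.astype(np.float32) / 255.0
    x = (x - 0.45) / 0.25
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def predict_proposals(image: np.ndarray, model: CountingNetwork) -> ProposalSet:
    """Run the network on one uint8 RGB image; eval mode, no graph."""
    was_training = model.training
    model.eval()
    try:
        with ad.no_grad():
            x = Tensor(normalize_image(image)[None])
            offsets, logits = model(x)
        refs = model.fused_grid(image.shape[0], image.shape[1])
        scores = 1.0 / (1.0 + np.exp(-logits.data[0]))
        return ProposalSet(PointSet(refs), offsets.data[0].astype(float), scores.astype(float))
    finally:
        if was_training:
            model.train()


def predict_points(image: np.ndarray, model: CountingNetwork, tau: float | None = None) -> PointSet:
    p = predict_proposals(image, model)
    return decode_points(p, model.cfg.confidence_threshold if tau is None else tau)


# ---------------------------------------------------------------------------
# Complexity accounting
# ---------------------------------------------------------------------------


@dataclass
class LayerSpec:
    c_in: int
    c_out: int
    kernel: int
    stride: int = 1
    output: tuple = (1, 1)  # (H_out, W_out)
    bias: bool = True


@dataclass
class ComplexityReport:
    parameters: int
    flops: int


def count_params(layers) -> int:
    """Conv parameter count: C_in * f^2 * C_out (+ C_out when biased)."""
    total = 0
    for l in layers:
        total += l.c_in * l.kernel * l.kernel * l.c_out + (l.c_out if l.bias else 0)
    return total


def count_flops(layers) -> int:
    """Conv FLOPs: 2 * H_out * W_out * (C_in * K^2 + bias) * C_out."""
    total = 0
    for l in layers:
        h, w = l.output
        total += 2 * h * w * (l.c_in * l.kernel * l.kernel + (1 if l.bias else 0)) * l.c_out
    return total


def complexity_report(layers) -> ComplexityReport:
    return ComplexityReport(count_params(layers), count_flops(layers))
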