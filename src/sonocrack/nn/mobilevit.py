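"""MobileViT-style lightweight vision transformer.

The network interleaves MobileNetV2 inverted-residual convolution
stages with MobileViT blocks.  A MobileViT block runs a local 3x3
convolution, projects to the transformer width d, unfolds the H x W x d
map into P patch positions by N patches, applies a transformer encoder
independently per position across the patch axis (global receptive
field at constant cost), folds back, projects to the input width, and
fuses with the block input through a 3x3 convolution after channel
concatenation.  Attention is scaled dot-product:
SoftMax(Q K^T / sqrt(d_k)) V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (
    Adam, BatchNorm2d, Conv2d, DepthwiseConv2d, LayerNorm, Linear, Module,
)

__all__ = [
    "AttentionInputs", "PatchTensorShapes", "attention", "unfold", "fold",
    "MV2Block", "MobileViTBlock", "MobileViT", "xxs_plan", "small_plan",
]


# ---------------------------------------------------------------------------
# reference functional ops on plain arrays

@dataclass
class AttentionInputs:
    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    d_k: int

    def __post_init__(self) -> None:
        if self.Q.shape[-1] != self.K.shape[-1] or self.Q.shape[-1] != self.d_k:
            raise ValueError("Q and K must share the key dimension d_k")
        if self.K.shape[-2] != self.V.shape[-2]:
            raise ValueError("K and V must share the row (token) count")


def attention(inputs: AttentionInputs) -> np.ndarray:
    """Scaled dot-product attention on plain arrays."""
    scores = inputs.Q @ np.swapaxes(inputs.K, -1, -2) / np.sqrt(inputs.d_k)
    z = scores - scores.max(axis=-1, keepdims=True)
    w = np.exp(z)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ inputs.V


@dataclass
class PatchTensorShapes:
    H: int
    W: int
    d: int
    h: int = 2
    w: int = 2

    def __post_init__(self) -> None:
        if self.H % self.h or self.W % self.w:
            raise ValueError("feature-map dims must be divisible by the patch dims")

    @property
    def P(self) -> int:
        return self.h * self.w

    @property
    def N(self) -> int:
        return (self.H // self.h) * (self.W // self.w)


def unfold(tensor: np.ndarray, shapes: PatchTensorShapes) -> np.ndarray:
    """(H, W, d) -> (P, N, d): gather position p of every patch across patches."""
    H, W, d, h, w = shapes.H, shapes.W, shapes.d, shapes.h, shapes.w
    if tensor.shape != (H, W, d):
        raise ValueError(f"tensor shape {tensor.shape} != {(H, W, d)}")
    x = tensor.reshape(H // h, h, W // w, w, d)
    return x.transpose(1, 3, 0, 2, 4).reshape(h * w, shapes.N, d)


def fold(tensor: np.ndarray, shapes: PatchTensorShapes) -> np.ndarray:
    """Inverse of :func:`unfold`; fold(unfold(X)) == X exactly."""
    H, W, d, h, w = shapes.H, shapes.W, shapes.d, shapes.h, shapes.w
    if tensor.shape != (shapes.P, shapes.N, d):
        raise ValueError(f"tensor shape {tensor.shape} != {(shapes.P, shapes.N, d)}")
    x = tensor.reshape(h, w, H // h, W // w, d)
    return x.transpose(2, 0, 3, 1, 4).reshape(H, W, d)


# ---------------------------------------------------------------------------
# differentiable modules

class ConvBnSilu(Module):
    def __init__(self, cin, cout, kernel, stride, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, padding=kernel // 2, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return ag.silu(self.bn(self.conv(x)))


class MV2Block(Module):
    """MobileNetV2 inverted residual: expand 1x1, depthwise 3x3, project 1x1."""

    def __init__(self, cin: int, cout: int, stride: int = 1, expand: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        hidden = cin * expand
        self.use_residual = stride == 1 and cin == cout
        self.expand = ConvBnSilu(cin, hidden, 1, 1, rng)
        self.dw = DepthwiseConv2d(hidden, 3, stride, padding=1, rng=rng)
        self.dw_bn = BatchNorm2d(hidden)
        self.project = Conv2d(hidden, cout, 1, 1, rng=rng)
        self.project_bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        y = self.expand(x)
        y = ag.silu(self.dw_bn(self.dw(y)))
        y = self.project_bn(self.project(y))
        if self.use_residual:
            y = ag.add(y, x)
        return y


class _MHA(Module):
    """Multi-head scaled dot-product attention over the token axis."""

    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads, self.dh = heads, dim // heads
        self.wq = Linear(dim, dim, rng=rng)
        self.wk = Linear(dim, dim, rng=rng)
        self.wv = Linear(dim, dim, rng=rng)
        self.out = Linear(dim, dim, rng=rng)

    def _split(self, t: Tensor, B: int, N: int) -> Tensor:
        t = ag.reshape(t, (B, N, self.heads, self.dh))
        return ag.transpose(t, (0, 2, 1, 3))            # (B, heads, N, dh)

    def forward(self, x: Tensor) -> Tensor:
        B, N, dim = x.shape
        q = self._split(self.wq(x), B, N)
        k = self._split(self.wk(x), B, N)
        v = self._split(self.wv(x), B, N)
        scores = ag.scale(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))),
                          1.0 / np.sqrt(self.dh))
        weights = ag.softmax(scores, axis=-1)
        ctx = ag.matmul(weights, v)                     # (B, heads, N, dh)
        ctx = ag.transpose(ctx, (0, 2, 1, 3))
        ctx = ag.reshape(ctx, (B, N, dim))
        return self.out(ctx)


class _EncoderBlock(Module):
    """One pre-norm transformer block: LN -> MHA -> +, LN -> MLP -> +."""

    def __init__(self, dim: int, heads: int, mlp_dim: int, rng):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = _MHA(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_dim, rng=rng)
        self.fc2 = Linear(mlp_dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.add(x, self.attn(self.ln1(x)))
        return ag.add(x, self.fc2(ag.silu(self.fc1(self.ln2(x)))))


class TransformerEncoder(Module):
    def __init__(self, dim: int, depth: int, heads: int, mlp_dim: int, rng):
        super().__init__()
        self.blocks = [_EncoderBlock(dim, heads, mlp_dim, rng)
                       for _ in range(depth)]

    def forward(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return x


def _unfold_batch(x: Tensor, h: int, w: int) -> tuple[Tensor, tuple]:
    """(B, H, W, d) -> (B*P, N, d) token batches, one per patch position."""
    B, H, W, d = x.shape
    t = ag.reshape(x, (B, H // h, h, W // w, w, d))
    t = ag.transpose(t, (0, 2, 4, 1, 3, 5))             # (B, h, w, H/h, W/w, d)
    N = (H // h) * (W // w)
    return ag.reshape(t, (B * h * w, N, d)), (B, H, W, d)


def _fold_batch(t: Tensor, h: int, w: int, shape: tuple) -> Tensor:
    B, H, W, d = shape
    t = ag.reshape(t, (B, h, w, H // h, W // w, d))
    t = ag.transpose(t, (0, 3, 1, 4, 2, 5))             # (B, H/h, h, W/w, w, d)
    return ag.reshape(t, (B, H, W, d))


class MobileViTBlock(Module):
    """Local conv -> unfold -> transformer across patches -> fold -> fuse."""

    def __init__(self, channels: int, dim: int, depth: int, heads: int,
                 mlp_dim: int, patch: tuple[int, int] = (2, 2),
                 rng: np.random.Generator | None = None,
                 transformer: TransformerEncoder | None = ...):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.patch = patch
        self.local = ConvBnSilu(channels, channels, 3, 1, rng)
        self.to_dim = Conv2d(channels, dim, 1, rng=rng)
        if transformer is ...:
            transformer = TransformerEncoder(dim, depth, heads, mlp_dim, rng)
        self.transformer = transformer                  # None = identity hook
        self.post_ln = LayerNorm(dim)
        self.from_dim = ConvBnSilu(dim, channels, 1, 1, rng)
        self.fuse = ConvBnSilu(2 * channels, channels, 3, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = self.patch
        y = self.local(x)
        y = self.to_dim(y)
        tokens, shape4 = _unfold_batch(y, h, w)
        if self.transformer is not None:
            tokens = self.post_ln(self.transformer(tokens))
        y = _fold_batch(tokens, h, w, (shape4[0], shape4[1], shape4[2],
                                       tokens.shape[-1]))
        y = self.from_dim(y)
        y = ag.concat([x, y], axis=-1)
        return self.fuse(y)


# ---------------------------------------------------------------------------
# channel plans and the full model

def xxs_plan() -> dict:
    """Full-scale plan (XXS-class capacity) for 256 x 256 inputs."""
    return {
        "stem": 16,
        "stages": [
            ("mv2", dict(cout=16, stride=1, expand=2)),
            ("mv2", dict(cout=24, stride=2, expand=2)),
            ("mv2", dict(cout=24, stride=1, expand=2)),
            ("mv2", dict(cout=24, stride=1, expand=2)),
            ("mv2", dict(cout=48, stride=2, expand=2)),
            ("mvit", dict(dim=64, depth=2, heads=2, mlp_dim=128)),
            ("mv2", dict(cout=64, stride=2, expand=2)),
            ("mvit", dict(dim=80, depth=4, heads=2, mlp_dim=160)),
            ("mv2", dict(cout=80, stride=2, expand=2)),
            ("mvit", dict(dim=96, depth=3, heads=2, mlp_dim=192)),
        ],
        "head": 320,
    }


def small_plan() -> dict:
    """Reduced plan for 64 x 64 inputs; the pipeline default on one CPU."""
    return {
        "stem": 16,
        "stages": [
            ("mv2", dict(cout=24, stride=2, expand=2)),
            ("mv2", dict(cout=24, stride=1, expand=2)),
            ("mvit", dict(dim=48, depth=2, heads=2, mlp_dim=96)),
            ("mv2", dict(cout=32, stride=2, expand=2)),
            ("mvit", dict(dim=64, depth=2, heads=2, mlp_dim=128)),
        ],
        "head": 128,
    }


PLANS = {"xxs": xxs_plan, "small": small_plan}


def plan_downsampling(plan: dict) -> int:
    """Total spatial downsampling factor: stem stride times MV2 strides."""
    down = 2
    for kind, kwargs in plan["stages"]:
        if kind == "mv2":
            down *= kwargs["stride"]
    return down


class MobileViT(Module):
    """Stem conv (stride 2) -> plan stages -> 1x1 head -> pool/flatten -> linear.

    ``head_mode='avg'`` is the canonical global-average-pool classifier.
    ``head_mode='flatten'`` feeds the flattened final feature map to the
    linear layer instead, keeping absolute canvas position available to
    the classifier — useful when class evidence sits at fixed image
    coordinates, as it does for the polyline encodings; it requires
    ``input_size`` to size the linear layer.
    """

    def __init__(self, plan: dict | str = "small", n_classes: int = 2,
                 patch: tuple[int, int] = (2, 2), seed: int = 0,
                 head_mode: str = "avg", input_size: int | None = None):
        super().__init__()
        if isinstance(plan, str):
            plan = PLANS[plan]()
        if head_mode not in ("avg", "flatten"):
            raise ValueError("head_mode must be 'avg' or 'flatten'")
        rng = np.random.default_rng(seed)
        self.head_mode = head_mode
        self.stem = ConvBnSilu(3, plan["stem"], 3, 2, rng)
        self.stages = []
        channels = plan["stem"]
        for kind, kwargs in plan["stages"]:
            if kind == "mv2":
                self.stages.append(MV2Block(channels, rng=rng, **kwargs))
                channels = kwargs["cout"]
            elif kind == "mvit":
                self.stages.append(
                    MobileViTBlock(channels, patch=patch, rng=rng, **kwargs)
                )
            else:
                raise ValueError(f"unknown stage kind {kind!r}")
        self.head = ConvBnSilu(channels, plan["head"], 1, 1, rng)
        if head_mode == "flatten":
            if input_size is None:
                raise ValueError("flatten head needs input_size")
            grid = input_size // plan_downsampling(plan)
            self.classifier = Linear(plan["head"] * grid * grid, n_classes,
                                     rng=rng)
        else:
            self.classifier = Linear(plan["head"], n_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, H, W, 3) in [0, 1] -> logits (B, n_classes)."""
        y = self.stem(x)
        for stage in self.stages:
            y = stage(y)
        y = self.head(y)
        if self.head_mode == "flatten":
            y = ag.reshape(y, (y.shape[0], -1))
        else:
            y = ag.mean_axes(y, (1, 2))                 # global average pool
        return self.classifier(y)

    def logits(self, images: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(images.astype(np.float32))).data
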