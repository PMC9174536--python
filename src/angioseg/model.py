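"""Lightweight bottleneck-residual U-Net for vessel segmentation.

The network is a U-Net variant whose convolutional stages are built from
MobileNetV2-style bottleneck residual blocks (1x1 expansion -> 3x3 depthwise
-> 1x1 linear projection, with a skip connection when stride is 1 and the
channel counts match).  Two attention mechanisms can be enabled:

* a *patch attention module* (PAM) after the deepest encoder map — softmax
  self-attention computed over non-overlapping ``n x n`` patches instead of
  pixels, which shrinks the attention matrix by a factor of ``n**4``;
* *squeeze-and-excitation* (SE) channel gates on the expanded representation
  inside every bottleneck block.

The default layout is frozen by calibration of the trainable-parameter
budget: stage widths (32, 40, 64, 128, 160), one bottleneck block per encoder
stage plus stride-2 transition blocks, two bridge blocks, and a narrow decoder
using 4x4 stride-2 transposed convolutions to widths (32, 32, 16, 8) followed
by skip concatenation and one bottleneck block per stage.  With expansion
factor t=2 this backbone holds 0.65 M trainable parameters (1.13/1.61/2.09 M
at t=4/6/8); SE adds 0.02 M, PAM adds 0.08 M, and the full model holds 0.75 M.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _autograd as ag
from ._autograd import (
    Adam,  # re-exported for train_eval  # noqa: F401
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Linear,
    Module,
    Parameter,
    Tensor,
    avg_pool2d,
    concat,
    softmax,
    upsample_nearest,
)

__all__ = [
    "BlockSpec",
    "PamConfig",
    "SeConfig",
    "NetConfig",
    "relu6",
    "bottleneck_forward",
    "block_param_count",
    "se_forward",
    "patch_split",
    "attention_map",
    "pam_forward",
    "build_network",
    "count_parameters",
    "BottleneckBlock",
    "SqueezeExcite",
    "PatchAttention",
    "BottleneckResidualUNet",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """Parameters of one bottleneck residual block.

    The residual connection is active iff ``stride == 1`` and
    ``in_channels == out_channels``.
    """

    in_channels: int
    out_channels: int
    stride: int = 1
    expansion: int = 2
    use_se: bool = False

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.expansion < 1:
            raise ValueError("expansion factor must be >= 1")

    @property
    def has_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


@dataclass(frozen=True)
class SeConfig:
    """Squeeze-and-excitation gate: hidden width = max(C // reduction, floor)."""

    reduction: int = 48
    floor: int = 4

    def hidden(self, channels: int) -> int:
        return max(channels // self.reduction, self.floor)


@dataclass(frozen=True)
class PamConfig:
    """Patch attention: ``patch_size`` must divide the attended map's dims."""

    patch_size: int = 2
    alpha_init: float = 0.0


@dataclass(frozen=True)
class NetConfig:
    """Frozen reference layout; see the module docstring for its calibration."""

    stage_widths: tuple = (32, 40, 64, 128, 160)
    up_widths: tuple = (32, 32, 16, 8)
    bridge_blocks: int = 2
    expansion: int = 2
    patch_size: int = 2
    use_pam: bool = True
    use_se: bool = True
    se: SeConfig = field(default_factory=SeConfig)
    num_classes: int = 1

    def __post_init__(self):
        if len(self.up_widths) != len(self.stage_widths) - 1:
            raise ValueError("need one up-convolution per resolution step")
        if any(w < 1 for w in self.stage_widths):
            raise ValueError("stage widths must be positive")
        if self.num_classes != 1:
            raise ValueError("only a single-channel sigmoid head is supported")

    @property
    def levels(self) -> int:
        return len(self.stage_widths)

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.levels - 1)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def relu6(x):
    """min(max(0, x), 6), element-wise; accepts numbers, arrays or Tensors."""
    if isinstance(x, Tensor):
        return x.relu6()
    return np.minimum(np.maximum(x, 0.0), 6.0)


def patch_split(x, n: int):
    """Average each non-overlapping ``n x n`` patch down to one position.

    Accepts an (H, W, C) numpy array (returns (H/n, W/n, C)) or a (B, C, H, W)
    Tensor (returns the pooled Tensor).
    """
    if isinstance(x, Tensor):
        return avg_pool2d(x, n)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected an (H, W, C) array")
    H, W, C = x.shape
    if H % n or W % n:
        raise ValueError(f"patch size {n} does not divide map dims {(H, W)}")
    return x.reshape(H // n, n, W // n, n, C).mean(axis=(1, 3))


def attention_map(q: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Row-stochastic patch-affinity matrix.

    ``s[m, n] = exp(q_m . k_n) / sum_n' exp(q_m . k_n')`` for (N, C) query and
    key matrices, stabilized by per-row max subtraction.
    """
    q = np.asarray(q, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("query/key channel mismatch")
    logits = q @ k.T
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class SqueezeExcite(Module):
    """Channel gate: global average pool -> FC/ReLU -> FC/sigmoid -> rescale."""

    def __init__(self, channels: int, cfg: SeConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = cfg.hidden(channels)
        self.fc1 = Linear(channels, hidden, bias=True, rng=rng)
        self.fc2 = Linear(hidden, channels, bias=True, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3))                      # squeeze: (B, C)
        h = self.fc1(z)
        h = Tensor._make(np.maximum(h.data, 0.0), (h,),
                         lambda g, h=h: h._accum(g * (h.data > 0)))
        s = self.fc2(h).sigmoid()                    # excitation: (B, C) in (0,1)
        B, C = s.shape
        return x * s.reshape(B, C, 1, 1)


def se_forward(x, se: SqueezeExcite):
    """Apply a squeeze-and-excitation gate; accepts (B, C, H, W) data."""
    return se(x if isinstance(x, Tensor) else Tensor(x))


class BottleneckBlock(Module):
    """Inverted residual block: expand -> depthwise -> linear projection."""

    def __init__(self, spec: BlockSpec, se_cfg: SeConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        k, kp, t = spec.in_channels, spec.out_channels, spec.expansion
        tk = t * k
        self.expand = Conv2d(k, tk, 1, rng=rng)
        self.bn1 = BatchNorm2d(tk)
        self.depthwise = Conv2d(tk, tk, 3, stride=spec.stride, padding=1,
                                groups=tk, rng=rng)
        self.bn2 = BatchNorm2d(tk)
        if spec.use_se:
            self.se = SqueezeExcite(tk, se_cfg or SeConfig(), rng=rng)
        self.project = Conv2d(tk, kp, 1, rng=rng)
        self.bn3 = BatchNorm2d(kp)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, "
                f"got {x.shape[1]}")
        y = relu6(self.bn1(self.expand(x)))
        y = relu6(self.bn2(self.depthwise(y)))
        if self.spec.use_se:
            y = self.se(y)
        y = self.bn3(self.project(y))
        if self.spec.has_residual:
            y = y + x
        return y


def bottleneck_forward(x, block: BottleneckBlock) -> Tensor:
    """Run one bottleneck residual block on (B, C, H, W) data."""
    return block(x if isinstance(x, Tensor) else Tensor(x))


def block_param_count(spec: BlockSpec, se_cfg: SeConfig | None = None) -> int:
    """Exact trainable-parameter count of one bottleneck block.

    Convolutions carry no bias (each is followed by batch normalization,
    contributing scale+shift = 2 parameters per channel).
    """
    k, kp, t = spec.in_channels, spec.out_channels, spec.expansion
    tk = t * k
    count = k * tk + 2 * tk          # 1x1 expansion + BN
    count += 9 * tk + 2 * tk         # 3x3 depthwise + BN
    count += tk * kp + 2 * kp        # 1x1 projection + BN
    if spec.use_se:
        h = (se_cfg or SeConfig()).hidden(tk)
        count += tk * h + h + h * tk + tk   # two FC layers with biases
    return count


class PatchAttention(Module):
    """Self-attention over non-overlapping patches of a feature map.

    Patches are reduced to positions by per-channel average pooling; q/k/v are
    1x1 convolutions at full channel width (no bias); the attended map is
    scaled by a learnable ``alpha`` (initialized so the module starts as an
    identity-plus-pooling path), added to the pooled map, upsampled back with
    nearest neighbour and added pixel-wise to the input.
    """

    def __init__(self, channels: int, cfg: PamConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.q = Conv2d(channels, channels, 1, rng=rng)
        self.k = Conv2d(channels, channels, 1, rng=rng)
        self.v = Conv2d(channels, channels, 1, rng=rng)
        self.alpha = Parameter(np.asarray(cfg.alpha_init, dtype=np.float32))
        #: shape of the most recent attention matrix, for size introspection
        self.last_attention_shape = None

    def __call__(self, x: Tensor) -> Tensor:
        n = self.cfg.patch_size
        B, C, H, W = x.shape
        if H % n or W % n:
            raise ValueError(
                f"patch size {n} does not divide the attended map {(H, W)}")
        pooled = avg_pool2d(x, n)                       # (B, C, h, w)
        h, w = H // n, W // n
        N = h * w
        q = self.q(pooled).reshape(B, C, N).transpose(0, 2, 1)   # (B, N, C)
        k = self.k(pooled).reshape(B, C, N).transpose(0, 2, 1)
        v = self.v(pooled).reshape(B, C, N).transpose(0, 2, 1)
        s = softmax(q @ k.transpose(0, 2, 1), axis=-1)  # (B, N, N), rows sum 1
        self.last_attention_shape = tuple(s.shape)
        attended = (s @ v).transpose(0, 2, 1).reshape(B, C, h, w)
        combined = self.alpha.reshape(1, 1, 1, 1) * attended + pooled
        return x + upsample_nearest(combined, n)


def pam_forward(x, pam: PatchAttention) -> Tensor:
    """Run a patch attention module on (B, C, H, W) data."""
    return pam(x if isinstance(x, Tensor) else Tensor(x))


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

class BottleneckResidualUNet(Module):
    """Encoder-decoder segmentation network built from bottleneck blocks."""

    def __init__(self, cfg: NetConfig = NetConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w = cfg.stage_widths
        t = cfg.expansion
        se_cfg = cfg.se if cfg.use_se else None

        def blk(cin, cout, stride=1):
            return BottleneckBlock(
                BlockSpec(cin, cout, stride, t, cfg.use_se), se_cfg, rng)

        # encoder: one block per stage, stride-2 transition between stages
        self.add_module("enc0", blk(1, w[0]))
        for i in range(len(w) - 1):
            self.add_module(f"down{i}", blk(w[i], w[i + 1], stride=2))
        for j in range(cfg.bridge_blocks):
            self.add_module(f"bridge{j}", blk(w[-1], w[-1]))

        if cfg.use_pam:
            self.add_module("pam", PatchAttention(
                w[-1], PamConfig(patch_size=cfg.patch_size), rng=rng))

        # decoder: 4x4 stride-2 transposed conv, skip concat, bottleneck block
        prev = w[-1]
        for j, i in enumerate(range(len(w) - 2, -1, -1)):
            u = cfg.up_widths[j]
            self.add_module(f"up{j}", ConvTranspose2d(prev, u, 4, 2, 1, rng=rng))
            self.add_module(f"upbn{j}", BatchNorm2d(u))
            self.add_module(f"dec{j}", blk(u + w[i], w[i]))
            prev = w[i]
        self.head = Conv2d(w[0], cfg.num_classes, 1, bias=True, rng=rng)

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        cfg = self.cfg
        f = cfg.downsample_factor
        B, C, H, W = x.shape
        if C != 1:
            raise ValueError("the network takes single-channel input")
        if H % f or W % f:
            raise ValueError(f"input dims must be divisible by {f}")

        skips = []
        y = self.enc0(x)
        for i in range(cfg.levels - 1):
            skips.append(y)
            y = getattr(self, f"down{i}")(y)
        for j in range(cfg.bridge_blocks):
            y = getattr(self, f"bridge{j}")(y)
        if cfg.use_pam:
            y = self.pam(y)
        for j in range(cfg.levels - 1):
            y = relu6(getattr(self, f"upbn{j}")(getattr(self, f"up{j}")(y)))
            y = concat([y, skips[-(j + 1)]], axis=1)
            y = getattr(self, f"dec{j}")(y)
        return self.head(y).sigmoid()

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one (H, W) image in eval mode."""
        was_training = self.training
        self.eval()
        try:
            out = self(image[None, None].astype(np.float32))
        finally:
            self.train(was_training)
        return out.data[0, 0]


def build_network(cfg: NetConfig = NetConfig(), seed: int = 0) -> BottleneckResidualUNet:
    """Construct the network with seeded Kaiming-uniform initialization."""
    return BottleneckResidualUNet(cfg, seed=seed)


def count_parameters(net: Module) -> int:
    """Exact count of trainable scalars in a built network."""
    return net.num_parameters()


def param_count_millions(net: Module) -> float:
    return round(count_parameters(net) / 1e6, 2)


def backbone_config(expansion: int = 2, use_pam: bool = False,
                    use_se: bool = False, patch_size: int = 2) -> NetConfig:
    """The frozen reference layout with the given ablation switches."""
    return replace(NetConfig(), expansion=expansion, use_pam=use_pam,
                   use_se=use_se, patch_size=patch_size)
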