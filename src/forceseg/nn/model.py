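"""The lightweight encoder–decoder segmentation network.

The encoder is a stack of inverted-residual blocks (1×1 expansion, depthwise
3×3, 1×1 linear projection, residual when shapes allow) — the factorized
convolution design that keeps the parameter count small. Feature maps are
tapped at strides 4, 8, 16 and 32, projected to a common width, resampled to
the stride-4 grid, and fused as a softmax-weighted sum with learnable
per-scale weights. A cross-scale attention block then lets every stride-4
position attend over the stride-32 tokens (queries from the fine map, keys
and values from the coarse one, scaled by √d), adding global context
residually. When enabled, a 2-channel inward force field is resampled to the
stride-4 grid and concatenated before the decoder, which upsamples back to
input resolution with a skip connection from the stem and ends in a sigmoid
cell-probability head.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from ..force_map import force_field_from_prediction
from .autograd import Tensor, concat, no_grad
from .layers import BatchNorm2d, Conv2d, DepthwiseConv2d, Dropout, Linear, Module

__all__ = [
    "ModelConfig",
    "FeatureMapSet",
    "ScaleWeights",
    "AttentionConfig",
    "BudgetExceededError",
    "MultiScaleAggregator",
    "CrossScaleAttention",
    "SegmentationModel",
    "build_model",
    "count_parameters",
    "segment",
]


class BudgetExceededError(RuntimeError):
    """Raised when a built model exceeds its trainable-parameter budget."""

    def __init__(self, count: int, budget: int):
        super().__init__(f"model has {count} trainable parameters, budget {budget}")
        self.count, self.budget = count, budget


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    `stage_channels` lists the widths after the stem and after each of the
    four stride-halving stages; taps for multi-scale aggregation sit at
    strides 4, 8, 16 and 32. The budget mirrors the 5.2 M-parameter figure
    the architecture is designed to stay under.
    """

    width_mult: float = 1.0
    stage_channels: tuple[int, int, int, int, int] = (16, 24, 32, 64, 96)
    blocks_per_stage: int = 2
    expand_ratio: int = 4
    agg_channels: int = 64
    attention_dim: int = 64
    decoder_channels: int = 32
    dropout: float = 0.1
    use_force_channels: bool = True
    param_budget: int = 5_200_000

    def scaled_channels(self) -> tuple[int, ...]:
        return tuple(max(4, int(round(c * self.width_mult))) for c in self.stage_channels)

    @staticmethod
    def ablation_scale(use_force_channels: bool = True) -> "ModelConfig":
        """Compact variant for small-image (e.g. 64×64) CPU training."""
        return ModelConfig(
            stage_channels=(8, 12, 16, 24, 32),
            blocks_per_stage=1,
            expand_ratio=3,
            agg_channels=24,
            attention_dim=16,
            decoder_channels=16,
            dropout=0.05,
            use_force_channels=use_force_channels,
        )


@dataclass
class FeatureMapSet:
    """Ordered multi-scale taps with strictly increasing strides."""

    maps: list[Tensor]
    strides: list[int]

    def __post_init__(self):
        if len(self.maps) != len(self.strides) or len(self.maps) < 2:
            raise ValueError("need >= 2 maps with matching strides")
        if any(b <= a for a, b in zip(self.strides, self.strides[1:])):
            raise ValueError("strides must be strictly increasing")

    @property
    def L(self) -> int:
        return len(self.maps)


@dataclass(frozen=True)
class AttentionConfig:
    d: int = 64
    pair: tuple[int, int] = (0, 3)  # (fine, coarse) tap indices

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("attention dimension must be >= 1")


class ScaleWeights(Module):
    """Learnable per-scale weights, softmax-normalized so they sum to 1."""

    def __init__(self, L: int):
        super().__init__()
        self.raw = Tensor(np.zeros(L), requires_grad=True)

    @property
    def normalized(self) -> np.ndarray:
        e = np.exp(self.raw.data - self.raw.data.max())
        return e / e.sum()

    def normalized_tensor(self) -> Tensor:
        return self.raw.softmax(axis=-1)


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, *, rng):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, kernel // 2, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class InvertedResidual(Module):
    """Expand (1×1) → depthwise 3×3 → project (1×1, linear), with residual."""

    def __init__(self, in_ch, out_ch, stride, expand_ratio, *, rng):
        super().__init__()
        hidden = in_ch * expand_ratio
        self.use_res = stride == 1 and in_ch == out_ch
        self.expand = (
            None if expand_ratio == 1 else Conv2d(in_ch, hidden, 1, bias=False, rng=rng)
        )
        self.bn0 = None if expand_ratio == 1 else BatchNorm2d(hidden)
        self.dw = DepthwiseConv2d(hidden, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(hidden)
        self.project = Conv2d(hidden, out_ch, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)

    def __call__(self, x):
        y = x
        if self.expand is not None:
            y = self.bn0(self.expand(y)).relu()
        y = self.bn1(self.dw(y)).relu()
        y = self.bn2(self.project(y))
        return (y + x) if self.use_res else y


class MultiScaleAggregator(Module):
    """Project each tap to a common width, resample to the finest tap's grid,
    and fuse with softmax-normalized learnable scale weights."""

    def __init__(self, in_channels: Sequence[int], agg_channels: int, *, rng):
        super().__init__()
        self.projections = [
            Conv2d(c, agg_channels, 1, bias=False, rng=rng) for c in in_channels
        ]
        self.bn = BatchNorm2d(agg_channels)
        self.scale_weights = ScaleWeights(len(in_channels))

    def __call__(self, features: FeatureMapSet) -> Tensor:
        if features.L != len(self.projections):
            raise ValueError(
                f"expected {len(self.projections)} feature maps, got {features.L}"
            )
        target_h, target_w = features.maps[0].shape[2:]
        alphas = self.scale_weights.normalized_tensor()
        fused = None
        for l, (fmap, proj) in enumerate(zip(features.maps, self.projections)):
            y = proj(fmap)
            if y.shape[2:] != (target_h, target_w):
                y = y.bilinear_resize(target_h, target_w)
            y = y * alphas[l]
            fused = y if fused is None else fused + y
        return self.bn(fused).relu()


class CrossScaleAttention(Module):
    """Scaled dot-product attention from a fine map onto a coarse map.

    Each spatial position is one token. Queries come from the fine map F_i,
    keys and values from the coarse map F_j; attention logits are scaled by
    √d; the attended output is projected back and added residually to F_i.
    """

    def __init__(self, fine_ch: int, coarse_ch: int, config: AttentionConfig, *, rng):
        super().__init__()
        self.config = config
        self.q = Linear(fine_ch, config.d, rng=rng)
        self.k = Linear(coarse_ch, config.d, rng=rng)
        self.v = Linear(coarse_ch, config.d, rng=rng)
        self.out = Linear(config.d, fine_ch, rng=rng)

    def attention_weights(self, fine: Tensor, coarse: Tensor) -> np.ndarray:
        """Row-stochastic attention matrix (for inspection/testing)."""
        return self._attend(fine, coarse, return_weights=True)[1]

    def _attend(self, fine: Tensor, coarse: Tensor, return_weights: bool = False):
        n, cf, hf, wf = fine.shape
        _, cc, hc, wc = coarse.shape
        ft = fine.reshape(n, cf, hf * wf).transpose(0, 2, 1)     # (N, Tq, Cf)
        ct = coarse.reshape(n, cc, hc * wc).transpose(0, 2, 1)   # (N, Tk, Cc)
        q, k, v = self.q(ft), self.k(ct), self.v(ct)
        logits = q.matmul(k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.config.d))
        attn = logits.softmax(axis=-1)
        out = attn.matmul(v)
        return out, attn.data if return_weights else None

    def __call__(self, fine: Tensor, coarse: Tensor) -> Tensor:
        n, cf, hf, wf = fine.shape
        out, _ = self._attend(fine, coarse)
        out = self.out(out)                                       # (N, Tq, Cf)
        out = out.transpose(0, 2, 1).reshape(n, cf, hf, wf)
        return fine + out


class SegmentationModel(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config.scaled_channels()
        e = config.expand_ratio

        self.stem = ConvBNReLU(3, c[0], 3, stride=2, rng=rng)     # stride 2
        self.stages = []
        for i in range(4):                                        # strides 4..32
            blocks = [InvertedResidual(c[i], c[i + 1], 2, e, rng=rng)]
            for _ in range(config.blocks_per_stage - 1):
                blocks.append(InvertedResidual(c[i + 1], c[i + 1], 1, e, rng=rng))
            self.stages.append(blocks)
        self.tap_strides = [4, 8, 16, 32]

        self.aggregator = MultiScaleAggregator(c[1:], config.agg_channels, rng=rng)
        self.attention = CrossScaleAttention(
            config.agg_channels, c[4], AttentionConfig(config.attention_dim), rng=rng
        )

        head_in = config.agg_channels + (2 if config.use_force_channels else 0)
        d = config.decoder_channels
        self.head1 = ConvBNReLU(head_in, d, 3, rng=rng)
        self.drop = Dropout(config.dropout, rng=np.random.default_rng(seed + 1))
        self.head2 = ConvBNReLU(d + c[0], d, 3, rng=rng)          # after stem skip
        self.final = Conv2d(d, 1, 3, padding=1, bias=True, rng=rng)

    # -- forward -----------------------------------------------------------

    def encode(self, x: Tensor) -> tuple[Tensor, FeatureMapSet]:
        skip = self.stem(x)
        taps, y = [], skip
        for blocks in self.stages:
            for b in blocks:
                y = b(y)
            taps.append(y)
        return skip, FeatureMapSet(taps, list(self.tap_strides))

    def __call__(self, x: Tensor, force: np.ndarray | None = None) -> Tensor:
        """Image batch (N,3,H,W) in [0,1] → probability map (N,H,W).

        `force` is an (N,2,H,W) force field (zeros when absent); it is
        resampled to the stride-4 grid and concatenated after aggregation.
        """
        n, _, h, w = x.shape
        skip, features = self.encode(x)
        agg = self.aggregator(features)
        agg = self.attention(agg, features.maps[-1])

        if self.config.use_force_channels:
            if force is None:
                force = np.zeros((n, 2, h, w))
            fmap = Tensor(force).bilinear_resize(agg.shape[2], agg.shape[3])
            agg = concat([agg, fmap], axis=1)

        y = self.drop(self.head1(agg))
        y = y.bilinear_resize(skip.shape[2], skip.shape[3])
        y = self.head2(concat([y, skip], axis=1))
        y = y.bilinear_resize(h, w)
        logits = self.final(y)
        return logits.sigmoid().reshape(n, h, w)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SegmentationModel:
    """Construct the model; fails loudly if the parameter budget is exceeded."""
    config = config or ModelConfig()
    model = SegmentationModel(config, seed)
    n = model.n_parameters()
    if n > config.param_budget:
        raise BudgetExceededError(n, config.param_budget)
    return model


def count_parameters(model: Module) -> int:
    """Number of trainable scalars in the model."""
    return model.n_parameters()


def _prepare_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB image")
    if img.max() > 1.0:
        img = img / 255.0
    return img.transpose(2, 0, 1)[None]


def segment(
    model: SegmentationModel,
    image: np.ndarray,
    two_pass: bool = True,
    threshold: float = 0.5,
    alpha: float = 1.0,
    return_instances: bool = False,
):
    """Run inference on one RGB image.

    Pass 1 runs with zero force channels. With `two_pass`, an inward force
    field is derived from the first-pass prediction (threshold, 8-connected
    components, centroids) and a second pass refines the probabilities.
    Instances, when requested, come from thresholding the final map and
    8-connected labeling.
    """
    model.eval()
    x = Tensor(_prepare_image(image))
    with no_grad():
        prob = model(x).data[0]
        if two_pass and model.config.use_force_channels:
            ff = force_field_from_prediction(prob, alpha=alpha, threshold=threshold)
            if np.any(ff.field):
                force = ff.field.transpose(2, 0, 1)[None]
                prob = model(x, force=force).data[0]
    if not return_instances:
        return prob
    labels, _ = ndimage.label(prob >= threshold, structure=np.ones((3, 3), int))
    return prob, labels
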