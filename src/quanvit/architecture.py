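"""Hybrid backbone + vision-transformer classifier in two modes.

The model is a four-stage bottleneck-residual backbone (the standard
3/4/6/3-block, 64/128/256/512-width layout) feeding a vision transformer.
In ``classical`` mode every backbone operator is a trainable convolution;
in ``quantum`` mode every convolution is replaced by a quanvolutional layer
with a frozen seeded angle bank, so the quantum backbone is a deterministic
parameter-free feature extractor and only the transformer and head train.

The final spatial feature map (7 x 7 x 2048 at full scale on a 224 input)
is tokenized one token per spatial cell through a learned linear projection;
learned positional embeddings are added and a learnable CLS token is
prepended.  An optional 2x nearest-neighbour upsampling switch yields the
196-token reading instead.  Classification comes from the CLS token through
LayerNorm + a linear head with a softmax over 2 (binary) or 4 classes.

A single ``scale`` multiplier in (0, 1] shrinks channel widths and the
transformer depth/width/heads together for desk-scale runs; ``scale=1``
reproduces the full published geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from . import nn
from .autograd import Tensor, concat, relu, softmax
from .nn import (
    Adam,
    BatchChannelNorm,
    Conv2d,
    LayerNorm,
    Linear,
    MaxPool2d,
    Module,
    Parameter,
    TransformerBlock,
    same_padding,
    trunc_normal,
)
from .quantum import EntanglementPattern
from .quanvolution import QuanvKernelBank, QuanvLayerSpec, output_shape, quanvolve, quanv_pool

__all__ = [
    "STAGE_BLOCKS",
    "STAGE_WIDTHS",
    "ViTSpec",
    "BackboneSpec",
    "ModelConfig",
    "ComplexityReport",
    "infer_stage_shapes",
    "build_model",
    "count_parameters",
    "count_macs",
    "HybridModel",
]

#: bottleneck blocks per stage and inner channel widths (stages 1-4)
STAGE_BLOCKS = (3, 4, 6, 3)
STAGE_WIDTHS = (64, 128, 256, 512)
STAGE_STRIDES = (1, 2, 2, 2)
EXPANSION = 4
STEM_CHANNELS = 64


def _scaled(value: int, scale: float) -> int:
    return max(1, int(round(value * scale)))


@dataclass(frozen=True)
class ViTSpec:
    """Transformer-encoder geometry."""

    dim: int = 768
    depth: int = 12
    heads: int = 12
    mlp_dim: int = 3072
    cls_token: bool = True
    upsample_tokens: bool = False  # 2x spatial upsampling -> 196-token reading

    def scaled(self, scale: float) -> "ViTSpec":
        heads = _scaled(self.heads, scale)
        dim = max(heads, _scaled(self.dim, scale))
        dim -= dim % heads  # keep divisibility
        return ViTSpec(
            dim=dim,
            depth=_scaled(self.depth, scale),
            heads=heads,
            mlp_dim=max(1, _scaled(self.mlp_dim, scale)),
            cls_token=self.cls_token,
            upsample_tokens=self.upsample_tokens,
        )


@dataclass(frozen=True)
class BackboneSpec:
    """Stage layout of the residual backbone."""

    blocks: tuple[int, ...] = STAGE_BLOCKS
    widths: tuple[int, ...] = STAGE_WIDTHS
    strides: tuple[int, ...] = STAGE_STRIDES
    stem_channels: int = STEM_CHANNELS
    mode: Literal["classical", "quantum"] = "classical"

    def __post_init__(self):
        if not (len(self.blocks) == len(self.widths) == len(self.strides)):
            raise ValueError("blocks/widths/strides must have equal length")


@dataclass(frozen=True)
class ModelConfig:
    """Complete description of one hybrid classifier build."""

    input_size: tuple[int, int, int] = (224, 224, 3)
    mode: Literal["classical", "quantum"] = "classical"
    n_classes: int = 2
    scale: float = 1.0
    vit: ViTSpec = field(default_factory=ViTSpec)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    use_norm: bool = True
    binary_single_logit: bool = False  # 1-logit sigmoid variant of the binary head
    seed: int = 0
    quanv_seed: int | None = None
    quanv_trainable: bool = False

    def __post_init__(self):
        if not (0 < self.scale <= 1):
            raise ValueError("scale must lie in (0, 1]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.mode not in ("classical", "quantum"):
            raise ValueError("mode must be 'classical' or 'quantum'")
        if self.backbone.mode != self.mode:
            object.__setattr__(
                self,
                "backbone",
                BackboneSpec(
                    self.backbone.blocks,
                    self.backbone.widths,
                    self.backbone.strides,
                    self.backbone.stem_channels,
                    self.mode,
                ),
            )

    @property
    def stage_channels(self) -> list[int]:
        return [_scaled(w, self.scale) for w in self.backbone.widths]

    @property
    def stem_out(self) -> int:
        return _scaled(self.backbone.stem_channels, self.scale)

    @property
    def vit_scaled(self) -> ViTSpec:
        return self.vit.scaled(self.scale)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d


def infer_stage_shapes(config: ModelConfig) -> dict[str, tuple]:
    """Per-stage output shapes from the configuration arithmetic alone.

    'same' padding with ceil(size/stride) outputs throughout, matching the
    published stage table (224 -> 112 -> 56 -> 56 -> 28 -> 14 -> 7 at full
    scale).
    """
    H, W, _ = config.input_size
    shapes: dict[str, tuple] = {"input": tuple(config.input_size)}

    def down(size: int, stride: int) -> int:
        return -(-size // stride)

    H, W = down(H, 2), down(W, 2)  # 7x7 stem conv, stride 2, same
    H, W = down(H, 2), down(W, 2)  # 3x3 pool, stride 2, same
    shapes["stage0"] = (H, W, config.stem_out)
    for i, (stride, c) in enumerate(zip(config.backbone.strides, config.stage_channels)):
        H, W = down(H, stride), down(W, stride)
        shapes[f"stage{i + 1}"] = (H, W, EXPANSION * c)
    vit = config.vit_scaled
    tokens = H * W * (4 if vit.upsample_tokens else 1)
    shapes["tokens"] = (tokens + (1 if vit.cls_token else 0), vit.dim)
    shapes["head"] = (1 if config.binary_single_logit and config.n_classes == 2
                      else config.n_classes,)
    return shapes


# ---------------------------------------------------------------------------
# classical backbone
# ---------------------------------------------------------------------------


class ClassicalBottleneck(Module):
    """1x1 -> 3x3 -> 1x1 residual bottleneck with projection shortcut."""

    def __init__(self, c_in: int, inner: int, stride: int,
                 rng: np.random.Generator, use_norm: bool):
        super().__init__()
        c_out = EXPANSION * inner
        self.conv1 = Conv2d(1, c_in, inner, rng, stride=1, bias=not use_norm)
        self.conv2 = Conv2d(3, inner, inner, rng, stride=stride, bias=not use_norm)
        self.conv3 = Conv2d(1, inner, c_out, rng, stride=1, bias=not use_norm)
        self.use_norm = use_norm
        if use_norm:
            self.norm1 = BatchChannelNorm(inner)
            self.norm2 = BatchChannelNorm(inner)
            # zero-init: the block starts as the identity map
            self.norm3 = BatchChannelNorm(c_out, zero_init=True)
        self.projection = None
        if stride != 1 or c_in != c_out:
            self.projection = Conv2d(1, c_in, c_out, rng, stride=stride,
                                     bias=not use_norm)
            self.proj_norm = BatchChannelNorm(c_out) if use_norm else None

    def forward(self, x: Tensor) -> Tensor:
        out = self.conv1(x)
        if self.use_norm:
            out = self.norm1(out)
        out = relu(out)
        out = self.conv2(out)
        if self.use_norm:
            out = self.norm2(out)
        out = relu(out)
        out = self.conv3(out)
        if self.use_norm:
            out = self.norm3(out)
        shortcut = x
        if self.projection is not None:
            shortcut = self.projection(x)
            if self.use_norm and self.proj_norm is not None:
                shortcut = self.proj_norm(shortcut)
        return relu(out + shortcut)


class ClassicalBackbone(Module):
    frozen = False

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        stem_c = config.stem_out
        self.stem_conv = Conv2d(7, config.input_size[2], stem_c, rng, stride=2,
                                bias=not config.use_norm)
        self.stem_norm = BatchChannelNorm(stem_c) if config.use_norm else None
        self.pool = MaxPool2d(3, 2, "same")
        self.stages: list[list[ClassicalBottleneck]] = []
        c_in = stem_c
        for n_blocks, inner, stride in zip(
            config.backbone.blocks, config.stage_channels, config.backbone.strides
        ):
            blocks = []
            for b in range(n_blocks):
                blocks.append(
                    ClassicalBottleneck(
                        c_in, inner, stride if b == 0 else 1, rng, config.use_norm
                    )
                )
                c_in = EXPANSION * inner
            self.stages.append(blocks)
        self.out_channels = c_in

    def forward(self, x: Tensor) -> Tensor:
        out = self.stem_conv(x)
        if self.stem_norm is not None:
            out = self.stem_norm(out)
        out = self.pool(relu(out))
        for blocks in self.stages:
            for block in blocks:
                out = block(out)
        return out


# ---------------------------------------------------------------------------
# quantum backbone
# ---------------------------------------------------------------------------


@dataclass
class QuanvLayer:
    """One frozen quanvolutional operator: spec + seeded angle bank."""

    spec: QuanvLayerSpec
    bank: QuanvKernelBank

    @classmethod
    def make(cls, kernel: int, n_filters: int, stride: int, seed: int,
             trainable: bool = False) -> "QuanvLayer":
        spec = QuanvLayerSpec(
            window=(kernel, kernel), stride=stride, padding="same",
            n_filters=n_filters,
            entanglement=EntanglementPattern.linear_chain(4),
        )
        return cls(spec, QuanvKernelBank.for_spec(spec, seed, trainable))

    def __call__(self, images: np.ndarray) -> np.ndarray:
        """Apply to a batch (N, H, W, C) -> (N, H_out, W_out, n_filters)."""
        return np.stack([quanvolve(img, self.spec, self.bank) for img in images])

    def circuit_evals(self, input_hw: tuple[int, int]) -> int:
        h, w, _ = output_shape(self.spec, input_hw)
        return h * w * self.spec.n_circuits


class FrozenChannelNorm:
    """Per-channel renormalization calibrated once, then frozen.

    Quanvolution readouts concentrate tightly around 1/2 (each circuit
    averages pooled window features, and channel averaging shrinks
    inter-sample differences), so a deep frozen stack would contract all
    inputs toward a constant.  This layer restores a healthy dynamic range:
    on the first (calibration) batch it records per-channel mean and spread,
    and thereafter maps activations to ``clip(0.5 + gain * (x - mu) / sd)``
    so every stage re-occupies the [0, 1] interval the angle encoding
    expects.  Statistics are data-derived but fixed after calibration, so
    features stay a deterministic function of (config, seed, training set).
    """

    def __init__(self, gain: float = 0.2, eps: float = 1e-8):
        self.gain = gain
        self.eps = eps
        self.mu: np.ndarray | None = None
        self.sd: np.ndarray | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.mu is None:
            self.mu = x.mean(axis=(0, 1, 2))
            self.sd = x.std(axis=(0, 1, 2)) + self.eps
        return np.clip(0.5 + self.gain * (x - self.mu) / self.sd, 0.0, 1.0)

    def reset(self) -> None:
        self.mu = self.sd = None


class FrozenStandardizer:
    """Per-channel z-scoring of frozen backbone features, calibrated once.

    Quanvolution maps stay inside [0, 1], so their inter-sample variation
    reaches the transformer embedded far below the static token structure;
    standardizing each channel on the first (training) batch and freezing
    the statistics gives the transformer an input whose sample-to-sample
    signal is on the scale its initialization expects.
    """

    def __init__(self, scale: float = 0.5, eps: float = 1e-8):
        self.scale = scale
        self.eps = eps
        self.mu: np.ndarray | None = None
        self.sd: np.ndarray | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.mu is None:
            self.mu = x.mean(axis=(0, 1, 2))
            self.sd = x.std(axis=(0, 1, 2)) + self.eps
        return (x - self.mu) / self.sd * self.scale

    def reset(self) -> None:
        self.mu = self.sd = None


class QuanvBottleneck:
    """Bottleneck block whose three operators are frozen quanvolutions.

    Activations are renormalized after the transformed path and the
    residual combination is a centred, identity-dominant update,
    ``norm(shortcut + PATH_WEIGHT * (path - 1/2))``.  A frozen random path
    adds variance that dilutes the shortcut's information at every block, so
    the path enters with a small fixed weight (the frozen-network analogue
    of SkipInit/ReZero residual scaling); the shortcut stays clean and
    inter-sample signal survives deep stacks while remaining in the [0, 1]
    encoding range.
    """

    PATH_WEIGHT = 0.35

    def __init__(self, c_in: int, inner: int, stride: int, seed_iter):
        c_out = EXPANSION * inner
        self.c_out = c_out
        self.stride = stride
        self.q1 = QuanvLayer.make(1, inner, 1, next(seed_iter))
        self.q2 = QuanvLayer.make(3, inner, stride, next(seed_iter))
        self.q3 = QuanvLayer.make(1, c_out, 1, next(seed_iter))
        self.norm1 = FrozenChannelNorm()
        self.norm2 = FrozenChannelNorm()
        self.norm3 = FrozenChannelNorm()
        self.out_norm = FrozenChannelNorm()
        self.project = stride != 1 or c_in != c_out

    @staticmethod
    def _pool_tile(x: np.ndarray, stride: int, c_out: int) -> np.ndarray:
        """Parameter-free downsampling shortcut: average-pool + channel tile.

        Keeps the identity path information-preserving where the classical
        network would use a learned 1x1 projection (a frozen random circuit
        there would scramble the shortcut and defeat its purpose).
        """
        n, h, w, c = x.shape
        if stride > 1:
            ho, wo = -(-h // stride), -(-w // stride)  # ceil, matching 'same'
            x = np.pad(
                x, ((0, 0), (0, ho * stride - h), (0, wo * stride - w), (0, 0)),
                mode="edge",
            )
            x = x.reshape(n, ho, stride, wo, stride, c).mean(axis=(2, 4))
        if c_out % x.shape[-1]:
            raise ValueError("channel tiling requires integer expansion")
        return np.tile(x, (1, 1, 1, c_out // x.shape[-1]))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        out = self.norm1(self.q1(x))
        out = self.norm2(self.q2(out))
        out = self.norm3(self.q3(out))
        if self.project:
            shortcut = self._pool_tile(x, self.stride, self.c_out)
        else:
            shortcut = x
        return self.out_norm(shortcut + self.PATH_WEIGHT * (out - 0.5))

    def norms(self):
        return [self.norm1, self.norm2, self.norm3, self.out_norm]

    def layers(self):
        return [self.q1, self.q2, self.q3]


class QuanvBackbone:
    """Fully quanvolutional feature extractor with frozen seeded banks.

    Contributes no trainable parameters; its forward pass is a pure
    deterministic function of (config, quanv seed, input), so features can
    be computed once and cached during training.
    """

    frozen = True
    training = False

    def __init__(self, config: ModelConfig, seed: int):
        ss = np.random.SeedSequence(seed)
        seeds = iter(int(s) % (2**31) for s in ss.generate_state(256))
        self.stem = QuanvLayer.make(7, config.stem_out, 2, next(seeds))
        self.stem_norm = FrozenChannelNorm()
        self.stages: list[list[QuanvBottleneck]] = []
        c_in = config.stem_out
        for n_blocks, inner, stride in zip(
            config.backbone.blocks, config.stage_channels, config.backbone.strides
        ):
            blocks = []
            for b in range(n_blocks):
                blocks.append(
                    QuanvBottleneck(c_in, inner, stride if b == 0 else 1, seeds)
                )
                c_in = EXPANSION * inner
            self.stages.append(blocks)
        self.out_channels = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.stem_norm(self.stem(x))
        out = np.stack([quanv_pool(m, (3, 3), 2, "same") for m in out])
        for blocks in self.stages:
            for block in blocks:
                out = block(out)
        return out

    __call__ = forward

    def reset_calibration(self) -> None:
        """Forget stored normalization statistics (next batch recalibrates)."""
        self.stem_norm.reset()
        for blocks in self.stages:
            for block in blocks:
                for norm in block.norms():
                    norm.reset()

    def parameters(self):
        return iter(())

    def n_parameters(self) -> int:
        return 0

    def all_layers(self) -> list[QuanvLayer]:
        layers = [self.stem]
        for blocks in self.stages:
            for block in blocks:
                layers.extend(block.layers())
        return layers

    def eval(self):
        return self

    def train(self, mode: bool = True):
        return self


# ---------------------------------------------------------------------------
# transformer head
# ---------------------------------------------------------------------------


class ViTHead(Module):
    """Patch embedding + positional encodings + CLS token + encoder + head."""

    def __init__(self, in_channels: int, n_tokens: int, vit: ViTSpec,
                 n_out: int, rng: np.random.Generator):
        super().__init__()
        self.vit = vit
        self.n_tokens = n_tokens
        self.patch_proj = Linear(in_channels, vit.dim, rng)
        seq = n_tokens + (1 if vit.cls_token else 0)
        self.pos_embed = Parameter(trunc_normal(rng, (1, seq, vit.dim)))
        self.cls = Parameter(trunc_normal(rng, (1, 1, vit.dim))) if vit.cls_token else None
        self.blocks = [
            TransformerBlock(vit.dim, vit.heads, vit.mlp_dim, rng)
            for _ in range(vit.depth)
        ]
        self.norm = LayerNorm(vit.dim)
        self.head = Linear(vit.dim, n_out, rng)

    def forward(self, features: Tensor) -> Tensor:
        """(N, H, W, C) feature map -> (N, n_out) logits."""
        n, h, w, c = features.shape
        if self.vit.upsample_tokens:
            # nearest-neighbour 2x spatial upsampling via index repetition
            features = features[:, np.repeat(np.arange(h), 2)]
            features = features[:, :, np.repeat(np.arange(w), 2)]
            h, w = 2 * h, 2 * w
        tokens = features.reshape(n, h * w, c)
        if h * w != self.n_tokens:
            raise ValueError(
                f"expected {self.n_tokens} tokens, got {h * w}; "
                "input size does not match the configured geometry"
            )
        x = self.patch_proj(tokens)
        if self.cls is not None:
            cls = Tensor(np.zeros((n, 1, self.vit.dim))) + self.cls
            x = concat([cls, x], axis=1)
        x = x + self.pos_embed
        for block in self.blocks:
            x = block(x)
        x = self.norm(x)
        pooled = x[:, 0, :] if self.cls is not None else x.mean(axis=1)
        return self.head(pooled)


class HybridModel(Module):
    """Backbone (classical or quantum) + ViT encoder + softmax head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.mode == "quantum":
            qseed = config.seed if config.quanv_seed is None else config.quanv_seed
            self.backbone = QuanvBackbone(config, qseed)
            self.feature_scaler = FrozenStandardizer()
        else:
            self.backbone = ClassicalBackbone(config, rng)
            self.feature_scaler = None
        shapes = infer_stage_shapes(config)
        h, w, c = shapes[f"stage{len(config.backbone.blocks)}"]
        vit = config.vit_scaled
        n_tokens = h * w * (4 if vit.upsample_tokens else 1)
        n_out = shapes["head"][0]
        self.vit_head = ViTHead(c, n_tokens, vit, n_out, rng)
        self.stage_shapes = shapes

    @property
    def backbone_frozen(self) -> bool:
        return getattr(self.backbone, "frozen", False)

    def backbone_features(self, images: np.ndarray) -> np.ndarray | Tensor:
        if self.backbone_frozen:
            feats = self.backbone(np.asarray(images, dtype=float))
            return self.feature_scaler(feats)
        return self.backbone(Tensor(images))

    def forward(self, images: np.ndarray) -> Tensor:
        feats = self.backbone_features(images)
        if isinstance(feats, np.ndarray):
            feats = Tensor(feats)
        return self.vit_head(feats)

    def head_forward(self, features: np.ndarray | Tensor) -> Tensor:
        if isinstance(features, np.ndarray):
            features = Tensor(features)
        return self.vit_head(features)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-class probabilities (rows sum to 1)."""
        self.eval()
        logits = self.forward(images)
        if logits.shape[-1] == 1:  # single-logit sigmoid head
            p1 = 1.0 / (1.0 + np.exp(-logits.data[:, 0]))
            return np.stack([1 - p1, p1], axis=1)
        return softmax(logits, axis=-1).data


def build_model(config: ModelConfig) -> HybridModel:
    """Construct the hybrid classifier described by ``config``."""
    return HybridModel(config)


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComplexityReport:
    """Trainable parameters, multiply-accumulates and circuit executions."""

    parameters: int
    macs: int
    flops: int
    circuit_evals: int

    def __post_init__(self):
        if self.flops != 2 * self.macs:
            raise ValueError("FLOPs must equal 2 x MACs by convention")

    def to_dict(self) -> dict:
        return asdict(self)


def count_parameters(model: Module | HybridModel) -> int:
    """Trainable scalar count (frozen quanvolution banks contribute none)."""
    return model.n_parameters()


def _conv_macs(kernel: int, c_in: int, c_out: int, out_hw: tuple[int, int]) -> int:
    return kernel * kernel * c_in * c_out * out_hw[0] * out_hw[1]


def count_macs(model: HybridModel, input_shape: tuple[int, int, int] | None = None
               ) -> ComplexityReport:
    """Per-forward-pass complexity for one image.

    Convolution MACs are k^2 * C_in * C_out * H_out * W_out; transformer
    MACs cover the QKV/out projections, attention scores and value mixing,
    and the MLP.  Quanvolutional layers execute circuits instead of MACs and
    are tallied separately as ``circuit_evals``.
    """
    config = model.config
    if input_shape is None:
        input_shape = config.input_size
    H, W, C = input_shape
    macs = 0
    circuit_evals = 0

    def down(size, stride):
        return -(-size // stride)

    h, w = down(H, 2), down(W, 2)
    stem_c = config.stem_out
    if config.mode == "quantum":
        circuit_evals += h * w * model.backbone.stem.spec.n_circuits
    else:
        macs += _conv_macs(7, C, stem_c, (h, w))
    h, w = down(h, 2), down(w, 2)  # stem pool
    c_in = stem_c
    for n_blocks, inner, stride in zip(
        config.backbone.blocks, config.stage_channels, config.backbone.strides
    ):
        c_out = EXPANSION * inner
        for b in range(n_blocks):
            s = stride if b == 0 else 1
            ho, wo = down(h, s), down(w, s)
            if config.mode == "quantum":
                circuit_evals += h * w * inner          # 1x1, pre-stride
                circuit_evals += ho * wo * inner        # 3x3 (strided)
                circuit_evals += ho * wo * c_out        # 1x1 expand
                # the downsampling shortcut is a parameter-free pool + tile
            else:
                macs += _conv_macs(1, c_in, inner, (h, w))
                macs += _conv_macs(3, inner, inner, (ho, wo))
                macs += _conv_macs(1, inner, c_out, (ho, wo))
                if s != 1 or c_in != c_out:
                    macs += _conv_macs(1, c_in, c_out, (ho, wo))
            h, w = ho, wo
            c_in = c_out
    vit = config.vit_scaled
    n_tokens = h * w * (4 if vit.upsample_tokens else 1)
    seq = n_tokens + (1 if vit.cls_token else 0)
    d = vit.dim
    macs += n_tokens * c_in * d  # patch projection
    per_block = (
        seq * d * 3 * d          # QKV projection
        + seq * seq * d          # attention scores
        + seq * seq * d          # value mixing
        + seq * d * d            # output projection
        + 2 * seq * d * vit.mlp_dim  # MLP
    )
    macs += vit.depth * per_block
    n_out = 1 if (config.binary_single_logit and config.n_classes == 2) else config.n_classes
    macs += d * n_out
    return ComplexityReport(
        parameters=count_parameters(model),
        macs=int(macs),
        flops=int(2 * macs),
        circuit_evals=int(circuit_evals),
    )
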