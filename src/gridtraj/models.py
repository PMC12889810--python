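"""The three grid classifiers: Vision Transformer, plain CNN, and ResNet.

All three accept the same contract — a batch of single-channel binary
occupancy grids, ``(B, 1, H, W)`` float input — and emit two logits
(normal vs abnormal).  Defaults reproduce the tabulated architectures on
128×128 input:

* **ViT** — 8×8 convolutional patch embedding with stride 8 into a
  128-dimensional token space (256 patches on 128×128), a learnable
  class token prepended and learnable positional embeddings added (257
  tokens), six pre-norm transformer encoder layers with GELU MLPs, a
  final layer normalization, and a linear head on the class token.
* **CNN** — three conv(3×3, same padding)+ReLU+maxpool(2×2) blocks with
  16/32/64 filters, flatten (16384 features on 128×128), FC 256 + ReLU,
  FC 2.
* **ResNet** — 7×7/2 stem to 16 channels with batch norm, 3×3/2 max
  pool, four stages of two residual blocks at 16/32/64/128 channels
  (stride-2, 1×1-projection transitions), global average pooling, FC 2.

The forward cost and all token/feature shapes depend only on (H, W,
patch size), never on trip length — the point of the fixed-size grid
representation.  Attention-head count (8) and MLP expansion (4×) follow
the standard ViT recipe where the tabulation is silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn

__all__ = [
    "ViTConfig",
    "CNNConfig",
    "ResNetConfig",
    "patchify",
    "unpatchify",
    "build_vit",
    "build_cnn",
    "build_resnet",
    "build_model",
]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViTConfig:
    input_hw: tuple[int, int] = (128, 128)
    patch_size: int = 8
    embed_dim: int = 128
    n_encoder_layers: int = 6
    n_heads: int = 8
    mlp_ratio: int = 4
    n_classes: int = 2

    def __post_init__(self) -> None:
        H, W = self.input_hw
        if H % self.patch_size or W % self.patch_size:
            raise ValueError(
                f"input {H}x{W} not divisible by patch size {self.patch_size}"
            )
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )

    @property
    def n_patches(self) -> int:
        H, W = self.input_hw
        return (H // self.patch_size) * (W // self.patch_size)

    @property
    def n_tokens(self) -> int:
        return self.n_patches + 1  # + class token


@dataclass(frozen=True)
class CNNConfig:
    input_hw: tuple[int, int] = (128, 128)
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    fc_width: int = 256
    n_classes: int = 2

    def __post_init__(self) -> None:
        H, W = self.input_hw
        f = self.pool_size ** len(self.conv_channels)
        if H % f or W % f:
            raise ValueError(f"input {H}x{W} not divisible by total pooling factor {f}")

    @property
    def flatten_features(self) -> int:
        H, W = self.input_hw
        f = self.pool_size ** len(self.conv_channels)
        return self.conv_channels[-1] * (H // f) * (W // f)


@dataclass(frozen=True)
class ResNetConfig:
    input_hw: tuple[int, int] = (128, 128)
    stem_channels: int = 16
    stage_channels: tuple[int, ...] = (16, 32, 64, 128)
    blocks_per_stage: int = 2
    n_classes: int = 2

    def __post_init__(self) -> None:
        H, W = self.input_hw
        # stem /2, pool /2, three stride-2 stage transitions
        f = 4 * 2 ** (len(self.stage_channels) - 1)
        if H % f or W % f:
            raise ValueError(f"input {H}x{W} too small for downsampling factor {f}")


# ---------------------------------------------------------------------------
# Patchify (exposed both as an operation and inside the ViT)
# ---------------------------------------------------------------------------

def patchify(grid_batch: np.ndarray, patch_size: int) -> np.ndarray:
    """Partition ``(B, 1, H, W)`` grids into flattened non-overlapping
    patches, ``(B, n_patches, patch_size**2)``.

    Patches are ordered row-major over the patch lattice and each patch
    is flattened row-major; the map is lossless (see :func:`unpatchify`).
    """
    if grid_batch.ndim != 4 or grid_batch.shape[1] != 1:
        raise ValueError(f"expected shape (B, 1, H, W), got {grid_batch.shape}")
    B, _, H, W = grid_batch.shape
    p = patch_size
    if H % p or W % p:
        raise ValueError(f"grid {H}x{W} not divisible by patch size {p}")
    x = grid_batch.reshape(B, H // p, p, W // p, p)
    return x.transpose(0, 1, 3, 2, 4).reshape(B, (H // p) * (W // p), p * p)


def unpatchify(patches: np.ndarray, grid_hw: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`patchify`."""
    B, n, pp = patches.shape
    H, W = grid_hw
    p = int(round(pp ** 0.5))
    if p * p != pp or n != (H // p) * (W // p):
        raise ValueError(f"patch stack {patches.shape} inconsistent with grid {H}x{W}")
    x = patches.reshape(B, H // p, W // p, p, p).transpose(0, 1, 3, 2, 4)
    return x.reshape(B, 1, H, W)


# ---------------------------------------------------------------------------
# ViT
# ---------------------------------------------------------------------------

class VisionTransformer(nn.Module):
    def __init__(self, config: ViTConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        d, p = config.embed_dim, config.patch_size
        # strided conv over 1 channel == per-patch linear projection
        self.patch_embed = nn.Conv2d(1, d, kernel_size=p, rng=rng, stride=p)
        self.cls_token = nn.Parameter(rng.normal(0.0, 0.02, size=(1, 1, d)), "cls")
        self.pos_embed = nn.Parameter(
            rng.normal(0.0, 0.02, size=(1, config.n_tokens, d)), "pos"
        )
        self.encoder = nn.Sequential(
            *[
                nn.TransformerEncoderLayer(d, config.n_heads, config.mlp_ratio, rng)
                for _ in range(config.n_encoder_layers)
            ]
        )
        self.norm = nn.LayerNorm(d)
        self.head = nn.Linear(d, config.n_classes, rng)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Token sequence after patch embedding, class token and
        positional embeddings: shape (B, n_tokens, embed_dim)."""
        B = x.shape[0]
        d = self.config.embed_dim
        tokens = (
            self.patch_embed.forward(x.astype(nn.DTYPE))
            .reshape(B, d, -1)
            .transpose(0, 2, 1)
        )
        cls = np.broadcast_to(self.cls_token.value, (B, 1, d))
        return np.concatenate([cls, tokens], axis=1) + self.pos_embed.value

    def forward(self, x: np.ndarray) -> np.ndarray:
        seq = self.embed(x)
        self._B = x.shape[0]
        encoded = self.norm.forward(self.encoder.forward(seq))
        self._n_tokens = encoded.shape[1]
        return self.head.forward(encoded[:, 0, :])

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        B = self._B
        d = self.config.embed_dim
        dcls_out = self.head.backward(dlogits)
        dencoded = np.zeros((B, self._n_tokens, d), dtype=nn.DTYPE)
        dencoded[:, 0, :] = dcls_out
        dseq = self.encoder.backward(self.norm.backward(dencoded))
        self.pos_embed.grad += dseq.sum(axis=0, keepdims=True)
        self.cls_token.grad += dseq[:, :1, :].sum(axis=0, keepdims=True)
        dtokens = dseq[:, 1:, :]  # (B, n_patches, d)
        H, W = self.config.input_hw
        p = self.config.patch_size
        dpatch = dtokens.transpose(0, 2, 1).reshape(B, d, H // p, W // p)
        return self.patch_embed.backward(dpatch)


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

class ConvNet(nn.Sequential):
    def __init__(self, config: CNNConfig, rng: np.random.Generator) -> None:
        layers: list[nn.Module] = []
        in_ch = 1
        pad = config.kernel_size // 2  # 'same' padding: conv preserves H, W
        for out_ch in config.conv_channels:
            layers += [
                nn.Conv2d(in_ch, out_ch, config.kernel_size, rng, padding=pad),
                nn.ReLU(),
                nn.MaxPool2d(config.pool_size),
            ]
            in_ch = out_ch
        layers += [
            nn.Flatten(),
            nn.Linear(config.flatten_features, config.fc_width, rng),
            nn.ReLU(),
            nn.Linear(config.fc_width, config.n_classes, rng),
        ]
        super().__init__(*layers)
        self.config = config

    def forward(self, x: np.ndarray) -> np.ndarray:
        return super().forward(x.astype(nn.DTYPE))


# ---------------------------------------------------------------------------
# ResNet
# ---------------------------------------------------------------------------

class ResidualBlock(nn.Module):
    """conv-BN-ReLU-conv-BN with identity (or 1×1 projection) shortcut."""

    def __init__(
        self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.relu2 = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.shortcut: Optional[nn.Sequential] = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch),
            )
        else:
            self.shortcut = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        branch = self.bn2.forward(
            self.conv2.forward(self.relu1.forward(self.bn1.forward(self.conv1.forward(x))))
        )
        sc = self.shortcut.forward(x) if self.shortcut is not None else x
        return self.relu2.forward(branch + sc)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu2.backward(dout)
        dbranch = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dsum))))
        )
        dsc = self.shortcut.backward(dsum) if self.shortcut is not None else dsum
        return dbranch + dsc


class ResNet(nn.Sequential):
    def __init__(self, config: ResNetConfig, rng: np.random.Generator) -> None:
        layers: list[nn.Module] = [
            nn.Conv2d(1, config.stem_channels, 7, rng, stride=2, padding=3, bias=False),
            nn.BatchNorm2d(config.stem_channels),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1),
        ]
        in_ch = config.stem_channels
        for stage_idx, out_ch in enumerate(config.stage_channels):
            stride = 1 if stage_idx == 0 else 2
            for block_idx in range(config.blocks_per_stage):
                layers.append(
                    ResidualBlock(in_ch, out_ch, stride if block_idx == 0 else 1, rng)
                )
                in_ch = out_ch
        layers += [
            nn.GlobalAvgPool2d(),
            nn.Linear(config.stage_channels[-1], config.n_classes, rng),
        ]
        super().__init__(*layers)
        self.config = config

    def forward(self, x: np.ndarray) -> np.ndarray:
        return super().forward(x.astype(nn.DTYPE))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_vit(config: ViTConfig = ViTConfig(), seed: int = 0) -> VisionTransformer:
    return VisionTransformer(config, np.random.default_rng(seed))


def build_cnn(config: CNNConfig = CNNConfig(), seed: int = 0) -> ConvNet:
    return ConvNet(config, np.random.default_rng(seed))


def build_resnet(config: ResNetConfig = ResNetConfig(), seed: int = 0) -> ResNet:
    return ResNet(config, np.random.default_rng(seed))


def build_model(
    name: str,
    input_hw: tuple[int, int] = (128, 128),
    seed: int = 0,
    **overrides,
) -> nn.Module:
    """Build a classifier by name ('vit', 'cnn' or 'resnet')."""
    if name == "vit":
        return build_vit(ViTConfig(input_hw=input_hw, **overrides), seed)
    if name == "cnn":
        return build_cnn(CNNConfig(input_hw=input_hw, **overrides), seed)
    if name == "resnet":
        return build_resnet(ResNetConfig(input_hw=input_hw, **overrides), seed)
    raise ValueError(f"unknown model {name!r}; expected 'vit', 'cnn' or 'resnet'")
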