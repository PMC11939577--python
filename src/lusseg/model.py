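"""Transformer-encoder / convolutional-decoder segmentation network.

The network follows the skip-free TransUNet-style design used for lung
ultrasound artifact segmentation: a ViT-Small/16 encoder turns the frame into
a 14x14 grid of 384-dimensional patch features (for the 224-pixel default),
and a lightweight decoder of four (2x upsample -> 3x3 conv -> batch norm ->
ReLU) stages plus a final 1x1 convolution maps that grid back to a
full-resolution single-channel logit map.  There are no encoder-decoder skip
connections, which is what brings the trainable parameter count down to about
23 million (21.7 M encoder + 1.27 M decoder).

Weights initialize randomly from a seed; encoder weights exported from a
self-supervised (MSN) checkpoint can optionally be loaded from a local
``.npz`` file, but nothing is downloaded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor, concatenate, no_grad
from .nn import (Adam, BatchNorm2d, Conv2d, LayerNorm, Linear, Module,
                 TransformerBlock, _trunc_normal)

__all__ = ["ModelConfig", "ViTEncoder", "ConvDecoder", "SegModel",
           "build_model", "count_trainable_parameters",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults reproduce the 23 M design)."""

    image_size: int = 224
    patch_size: int = 16
    embed_dim: int = 384
    depth: int = 12
    num_heads: int = 6
    mlp_ratio: float = 4.0
    decoder_channels: list[int] = field(default_factory=lambda: [256, 128, 64, 32])
    out_channels: int = 1
    in_channels: int = 3          # grayscale input is replicated to match
    pretrained: bool = False
    pretrained_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        grid = self.image_size // self.patch_size
        if grid * 2 ** len(self.decoder_channels) != self.image_size:
            raise ValueError(
                f"decoder needs {int(math.log2(self.image_size / grid))} "
                f"upsampling stages to reach {self.image_size} from a "
                f"{grid}-wide token grid; got {len(self.decoder_channels)}")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size ** 2


class ViTEncoder(Module):
    """ViT-Small-style encoder; returns patch tokens as a spatial grid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.embed_dim
        self.cfg = cfg
        self.patch_embed = Linear(cfg.in_channels * cfg.patch_size ** 2, d, rng)
        self.cls_token = Tensor(_trunc_normal(rng, (1, 1, d)), requires_grad=True)
        self.pos_embed = Tensor(_trunc_normal(rng, (1, cfg.num_patches + 1, d)),
                                requires_grad=True)
        self.blocks = [TransformerBlock(d, cfg.num_heads, cfg.mlp_ratio, rng)
                       for _ in range(cfg.depth)]
        self.norm = LayerNorm(d)

    def _patchify(self, x: Tensor) -> Tensor:
        """(B, C, H, W) -> (B, N, C*p*p), row-major patch order."""
        cfg = self.cfg
        B, C, H, W = x.shape
        p, g = cfg.patch_size, H // cfg.patch_size
        x = x.reshape(B, C, g, p, g, p)
        x = x.transpose(0, 2, 4, 1, 3, 5)        # (B, gh, gw, C, p, p)
        return x.reshape(B, g * g, C * p * p)

    def forward(self, x: Tensor) -> Tensor:
        """Encode to a feature grid of shape (B, embed_dim, g, g)."""
        cfg = self.cfg
        B = x.shape[0]
        g = x.shape[2] // cfg.patch_size
        tokens = self.patch_embed(self._patchify(x))
        cls = self.cls_token.broadcast_to((B, 1, cfg.embed_dim))
        tokens = concatenate([cls, tokens], axis=1)
        tokens = tokens + self.pos_embed
        for blk in self.blocks:
            tokens = blk(tokens)
        tokens = self.norm(tokens)
        patch_tokens = tokens[:, 1:, :]           # drop the class token
        # row-major reshape back to the coarse spatial grid
        grid = patch_tokens.reshape(B, g, g, cfg.embed_dim)
        return grid.transpose(0, 3, 1, 2)


class ConvDecoder(Module):
    """Skip-free decoder: per stage 2x upsample -> 3x3 conv -> BN -> ReLU."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        chans = [cfg.embed_dim] + list(cfg.decoder_channels)
        self.convs = [Conv2d(cin, cout, 3, rng)
                      for cin, cout in zip(chans[:-1], chans[1:])]
        self.norms = [BatchNorm2d(c) for c in cfg.decoder_channels]
        self.head = Conv2d(cfg.decoder_channels[-1], cfg.out_channels, 1, rng)

    def forward(self, feat: Tensor) -> Tensor:
        x = feat
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x.upsample2x())).relu()
        return self.head(x)


class SegModel(Module):
    """Full encoder-decoder network producing a single-channel logit map."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.encoder = ViTEncoder(cfg, rng)
        self.decoder = ConvDecoder(cfg, rng)
        # bias the head toward the background class prior so that early
        # predictions are sparse (line artifacts cover a small image fraction)
        self.decoder.head.bias.data[:] = -2.0

    @staticmethod
    def prepare_input(img: np.ndarray, in_channels: int = 3) -> Tensor:
        """Grayscale [0,1] array(s) -> centered (B, C, H, W) tensor."""
        arr = np.asarray(img, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError("expected (H, W) or (B, H, W) grayscale input")
        arr = np.repeat(arr[:, None], in_channels, axis=1)
        return Tensor((arr - 0.5) / 0.5)

    def encode(self, img: np.ndarray | Tensor) -> Tensor:
        x = img if isinstance(img, Tensor) else \
            self.prepare_input(img, self.cfg.in_channels)
        return self.encoder(x)

    def forward(self, img: np.ndarray | Tensor) -> Tensor:
        return self.decoder(self.encode(img))

    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        """Inference-mode foreground probabilities, shape (B, H, W)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(img)
        finally:
            self.train(was_training)
        return 1.0 / (1.0 + np.exp(-logits.data[:, 0]))


def build_model(cfg: ModelConfig | None = None) -> SegModel:
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(cfg.seed)
    model = SegModel(cfg, rng)
    if cfg.pretrained:
        if not cfg.pretrained_path or not Path(cfg.pretrained_path).exists():
            raise FileNotFoundError(
                "pretrained=True requires pretrained_path pointing to a local "
                ".npz encoder state dict (no weights are downloaded)")
        state = dict(np.load(cfg.pretrained_path))
        model.encoder.load_state_dict(state)
    return model


def count_trainable_parameters(model_or_cfg: SegModel | ModelConfig | None = None
                               ) -> int:
    """Exact number of trainable scalars in encoder plus decoder."""
    if isinstance(model_or_cfg, SegModel):
        model = model_or_cfg
    else:
        model = build_model(model_or_cfg)
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: SegModel, path: str | Path) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(path: str | Path, cfg: ModelConfig | None = None) -> SegModel:
    cfg = cfg or ModelConfig()
    model = build_model(cfg)
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model


# re-export for layers that want a fresh optimizer without importing nn
__all__.append("Adam")
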