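"""Vision-transformer encoder and the shallow heads trained on top of it.

The classification network has four parts:

* **encoder** — a ViT: the image is cut into non-overlapping ``P x P``
  patches (``N = H*W / P**2`` of them), each linearly embedded, position
  embeddings added, and the token sequence passed through pre-norm
  transformer blocks.  The output tokens, reshaped onto the patch grid,
  form the feature map ``f`` of shape ``(encoder_dim, H/P, W/P)``.
* **contrastive head** — a small MLP used only during contrastive
  pretraining and discarded afterwards.
* **projector** — GAP over the patch grid followed by a shallow MLP
  producing the projected feature ``m``.
* **classifier** — a shallow MLP mapping ``m`` to class logits ``z``.

Initialization: the patch embedding (a convolution in disguise) is
Kaiming-initialized, all other linear layers Xavier-initialized, and
normalization layers start at scale one / shift zero.

The full-scale configuration (224x224 input, 16-pixel patches, 768-dim
encoder, 192-dim projection, 5 classes) matches the published model; a
tiny desk-scale configuration with the identical block structure is used
for experiments that must run on a CPU in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AdamW,  # noqa: F401  (re-exported for convenience)
    BatchNorm1d,
    GELU,
    Linear,
    LayerNorm,
    Module,
    Parameter,
    Sequential,
    Tensor,
    TransformerBlock,
    no_grad,
)

__all__ = [
    "ModelConfig",
    "ModelBundle",
    "ViTEncoder",
    "build_model",
    "classify",
    "encode",
    "freeze_encoder",
    "patch_count",
    "pool_project",
]


@dataclass(frozen=True)
class ModelConfig:
    image_height: int = 224
    image_width: int = 224
    channels: int = 3
    patch_size: int = 16
    encoder_dim: int = 768
    encoder_depth: int = 12
    encoder_heads: int = 12
    projector_dim: int = 192
    projector_hidden: int = 384
    classifier_hidden: int = 96
    contrastive_dim: int = 128
    num_classes: int = 5

    def __post_init__(self):
        if self.image_height % self.patch_size or self.image_width % self.patch_size:
            raise ValueError("image size must be divisible by patch size")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        for name in ("image_height", "image_width", "channels", "patch_size",
                     "encoder_dim", "encoder_depth", "encoder_heads",
                     "projector_dim", "projector_hidden", "classifier_hidden",
                     "contrastive_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.encoder_dim % self.encoder_heads:
            raise ValueError("encoder_dim must be divisible by encoder_heads")

    @property
    def grid_height(self) -> int:
        return self.image_height // self.patch_size

    @property
    def grid_width(self) -> int:
        return self.image_width // self.patch_size

    @classmethod
    def full_scale(cls, num_classes: int = 5) -> "ModelConfig":
        return cls(num_classes=num_classes)

    @classmethod
    def tiny(cls, image_size: int = 32, channels: int = 1, patch_size: int = 8,
             encoder_dim: int = 64, encoder_depth: int = 2,
             encoder_heads: int = 4, num_classes: int = 5) -> "ModelConfig":
        return cls(image_height=image_size, image_width=image_size,
                   channels=channels, patch_size=patch_size,
                   encoder_dim=encoder_dim, encoder_depth=encoder_depth,
                   encoder_heads=encoder_heads, projector_dim=32,
                   projector_hidden=48, classifier_hidden=32,
                   contrastive_dim=32, num_classes=num_classes)


def patch_count(cfg: ModelConfig) -> int:
    """Number of ViT patches, ``N = H W / P^2``."""
    return cfg.grid_height * cfg.grid_width


def _patchify(images: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """(B, H, W, C) float array -> (B, N, P*P*C) patch matrix."""
    if images.ndim == 3:
        images = images[..., None]
    B, H, W, C = images.shape
    if (H, W, C) != (cfg.image_height, cfg.image_width, cfg.channels):
        raise ValueError(
            f"input shape {(H, W, C)} does not match config "
            f"{(cfg.image_height, cfg.image_width, cfg.channels)}")
    P = cfg.patch_size
    gh, gw = cfg.grid_height, cfg.grid_width
    x = images.reshape(B, gh, P, gw, P, C)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(B, gh * gw, P * P * C)


class ViTEncoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        n = patch_count(cfg)
        self.patch_embed = Linear(cfg.patch_size ** 2 * cfg.channels,
                                  cfg.encoder_dim, rng, kaiming=True)
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, size=(n, cfg.encoder_dim)))
        self.blocks = [TransformerBlock(cfg.encoder_dim, cfg.encoder_heads, rng)
                       for _ in range(cfg.encoder_depth)]
        self.norm = LayerNorm(cfg.encoder_dim)

    def forward(self, images: np.ndarray) -> Tensor:
        """Raw image batch -> token Tensor of shape (B, N, encoder_dim)."""
        patches = _patchify(np.asarray(images, dtype=np.float32), self.cfg)
        x = self.patch_embed(Tensor(patches)) + self.pos_embed
        for blk in self.blocks:
            x = blk(x)
        return self.norm(x)


def _make_projector(cfg: ModelConfig, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Linear(cfg.encoder_dim, cfg.projector_hidden, rng),
        GELU(),
        BatchNorm1d(cfg.projector_hidden),
        Linear(cfg.projector_hidden, cfg.projector_dim, rng),
    )


def _make_classifier(cfg: ModelConfig, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Linear(cfg.projector_dim, cfg.classifier_hidden, rng),
        GELU(),
        Linear(cfg.classifier_hidden, cfg.num_classes, rng),
    )


def _make_contrastive_head(cfg: ModelConfig, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Linear(cfg.encoder_dim, cfg.encoder_dim, rng),
        GELU(),
        Linear(cfg.encoder_dim, cfg.contrastive_dim, rng),
    )


@dataclass
class ModelBundle:
    """Encoder plus heads, with per-component freeze flags."""

    cfg: ModelConfig
    encoder: ViTEncoder
    contrastive_head: Sequential | None
    projector: Sequential
    classifier: Sequential
    frozen: dict = field(default_factory=lambda: {"encoder": False})

    def encoder_checksum(self) -> str:
        return self.encoder.checksum()

    def head_checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(self.projector.checksum().encode())
        h.update(self.classifier.checksum().encode())
        return h.hexdigest()

    def trainable_parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        if not self.frozen.get("encoder", False):
            params += self.encoder.parameters()
            if self.contrastive_head is not None:
                params += self.contrastive_head.parameters()
        else:
            params += self.projector.parameters()
            params += self.classifier.parameters()
        return params

    def eval(self) -> "ModelBundle":
        for m in (self.encoder, self.projector, self.classifier):
            m.eval()
        if self.contrastive_head is not None:
            self.contrastive_head.eval()
        return self

    def train(self) -> "ModelBundle":
        for m in (self.encoder, self.projector, self.classifier):
            m.train()
        if self.contrastive_head is not None:
            self.contrastive_head.train()
        return self

    def set_qmode(self, mode: str) -> "ModelBundle":
        for m in (self.encoder, self.projector, self.classifier):
            m.set_qmode(mode)
        return self


def build_model(cfg: ModelConfig, seed: int = 0) -> ModelBundle:
    """Build and initialize a fresh model; reproducible under ``seed``."""
    root = np.random.SeedSequence(seed)
    r_enc, r_con, r_proj, r_cls = [np.random.default_rng(s)
                                   for s in root.spawn(4)]
    return ModelBundle(
        cfg=cfg,
        encoder=ViTEncoder(cfg, r_enc),
        contrastive_head=_make_contrastive_head(cfg, r_con),
        projector=_make_projector(cfg, r_proj),
        classifier=_make_classifier(cfg, r_cls),
    )


def freeze_encoder(bundle: ModelBundle) -> ModelBundle:
    """Exclude every encoder parameter from optimization, permanently."""
    bundle.frozen["encoder"] = True
    for p in bundle.encoder.parameters():
        p.requires_grad = False
    return bundle


# ----------------------------------------------------------------------
# numpy-facing inference ops
# ----------------------------------------------------------------------

def encode(images: np.ndarray, bundle: ModelBundle) -> np.ndarray:
    """Images -> feature maps of shape (B, encoder_dim, H/P, W/P)."""
    cfg = bundle.cfg
    with no_grad():
        tokens = bundle.encoder(images).data
    B = tokens.shape[0]
    return (tokens.reshape(B, cfg.grid_height, cfg.grid_width, cfg.encoder_dim)
            .transpose(0, 3, 1, 2))


def global_average_pool(feature_maps: np.ndarray) -> np.ndarray:
    """(B, D, gh, gw) -> (B, D), the mean over the patch grid."""
    return feature_maps.mean(axis=(2, 3))


def pool_project(feature_maps: np.ndarray, bundle: ModelBundle) -> np.ndarray:
    """GAP then projector: feature maps -> projected vectors ``m``."""
    f = np.asarray(feature_maps)
    squeeze = f.ndim == 3
    if squeeze:
        f = f[None]
    pooled = global_average_pool(f)
    prev = bundle.projector.training
    bundle.projector.eval()
    try:
        with no_grad():
            out = bundle.projector(Tensor(pooled)).data
    finally:
        bundle.projector.train(prev)
    return out[0] if squeeze else out


def classify(m: np.ndarray, bundle: ModelBundle) -> np.ndarray:
    """Projected vectors ``m`` -> logits ``z`` (B, num_classes)."""
    m = np.asarray(m)
    if m.shape[-1] != bundle.cfg.projector_dim:
        raise ValueError("projected vector length does not match config")
    squeeze = m.ndim == 1
    if squeeze:
        m = m[None]
    with no_grad():
        out = bundle.classifier(Tensor(m)).data
    return out[0] if squeeze else out
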