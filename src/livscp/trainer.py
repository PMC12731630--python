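"""Two-stage training: contrastive pretraining, then frozen-encoder heads.

Stage 1 (``pretrain_scp``) optimizes the encoder plus a throwaway
contrastive head with the class-weighted supervised contrastive loss on
two-view augmented batches.  Stage 2 (``train_heads``) freezes the
encoder, caches its pooled features once, and trains the projector and
classifier with plain (unweighted) cross-entropy.  The supervised
baseline (``train_sl_baseline``) runs stage 2 on an encoder that never
saw stage 1, so the only difference between the two pipelines is the
pretraining objective.

Optimization settings follow the published recipe: AdamW with learning
rate 3e-4 and decoupled weight decay 1e-4, temperature 0.07, at most 50
epochs with validation-loss early stopping (patience 5) and best-epoch
weight restoration.  Stage-2 features are cached un-augmented: with the
encoder frozen and the heads shallow, augmentation buys little and the
caching makes head training orders of magnitude cheaper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .contrastive import ClassWeights, compute_class_weights, supcon_loss_tensor
from .datapipe import AugmentationConfig, LabeledImageSet, two_view_batch
from .model import ModelBundle, freeze_encoder, global_average_pool, encode
from .nn import AdamW, Tensor, no_grad

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "early_stop",
    "encode_pooled",
    "pretrain_scp",
    "train_heads",
    "train_heads_on_features",
    "train_sl_baseline",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    weight_decay: float = 1e-4
    temperature: float = 0.07
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 16
    seed: int = 0
    stage: str = ""

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("learning rate and weight decay must be >= 0")
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def __len__(self) -> int:
        return len(self.train_loss)


def early_stop(val_losses, patience: int) -> tuple[bool, int]:
    """Early-stopping rule on a validation-loss trace.

    Returns ``(stop, best_epoch)`` with ``best_epoch`` the 0-based index
    of the smallest validation loss (ties break to the earliest epoch);
    training stops once ``patience`` epochs have elapsed since the best.
    """
    losses = list(val_losses)
    if not losses:
        raise ValueError("history is empty")
    best = int(np.argmin(losses))  # argmin takes the first minimum
    return (len(losses) - 1 - best) >= patience, best


def _l2_normalize(z: Tensor) -> Tensor:
    sq = (z * z).sum(axis=-1, keepdims=True)
    return z / ((sq + 1e-12) ** 0.5)


def _contrastive_forward(bundle: ModelBundle, views: np.ndarray,
                         labels: np.ndarray, tau: float,
                         sample_w: np.ndarray | None) -> Tensor:
    tokens = bundle.encoder(views)            # (B, N, D)
    pooled = tokens.mean(axis=1)              # GAP over the patch grid
    z = _l2_normalize(bundle.contrastive_head(pooled))
    return supcon_loss_tensor(z, labels, tau, sample_w)


def _check_val_classes(train_set: LabeledImageSet, val_set: LabeledImageSet) -> None:
    missing = set(np.unique(train_set.labels)) - set(np.unique(val_set.labels))
    if missing:
        warnings.warn(f"validation set missing train classes {sorted(missing)}")


def pretrain_scp(bundle: ModelBundle, train_set: LabeledImageSet,
                 val_set: LabeledImageSet, weights: ClassWeights,
                 cfg: TrainConfig,
                 aug: AugmentationConfig | None = None) -> tuple[ModelBundle, TrainHistory]:
    """Stage 1: class-weighted contrastive pretraining of the encoder.

    ``weights`` must come from the training-split counts only.  Early
    stops on the validation contrastive loss; the best-epoch weights are
    restored and the contrastive head is discarded from the returned
    bundle.
    """
    if bundle.frozen.get("encoder", False):
        raise ValueError("cannot pretrain a frozen encoder")
    if len(train_set) == 0:
        raise ValueError("empty training set")
    _check_val_classes(train_set, val_set)
    aug = aug if aug is not None else AugmentationConfig()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    opt = AdamW(bundle.encoder.parameters() + bundle.contrastive_head.parameters(),
                lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state = None
    steps = max(1, math.ceil(len(train_set) / cfg.batch_size))
    bundle.train()
    w_lookup = weights.weights
    for epoch in range(cfg.max_epochs):
        epoch_losses = []
        for _ in range(steps):
            views, labels = two_view_batch(train_set, cfg.batch_size, aug, rng)
            loss = _contrastive_forward(bundle, views, labels, cfg.temperature,
                                        w_lookup[labels])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(
            _validation_contrastive_loss(bundle, val_set, weights, cfg, aug))
        stop, best = early_stop(history.val_loss, cfg.patience)
        if best == epoch:
            best_state = (bundle.encoder.state_dict(),
                          bundle.contrastive_head.state_dict())
        if stop:
            history.stop_reason = "early_stop"
            break
    else:
        history.stop_reason = "max_epochs"
    history.best_epoch = int(np.argmin(history.val_loss))
    if best_state is not None:
        bundle.encoder.load_state_dict(best_state[0])
        bundle.contrastive_head.load_state_dict(best_state[1])
    bundle.contrastive_head = None  # stage-1 head is discarded
    return bundle, history


def _validation_contrastive_loss(bundle: ModelBundle, val_set: LabeledImageSet,
                                 weights: ClassWeights, cfg: TrainConfig,
                                 aug: AugmentationConfig) -> float:
    # fixed augmentation seed so epochs see identical validation batches
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    n_batches = max(1, math.ceil(len(val_set) / cfg.batch_size))
    losses = []
    with no_grad():
        for _ in range(n_batches):
            views, labels = two_view_batch(val_set, min(cfg.batch_size,
                                                        len(val_set)), aug, rng)
            loss = _contrastive_forward(bundle, views, labels, cfg.temperature,
                                        weights.weights[labels])
            losses.append(loss.item())
    return float(np.mean(losses))


# ----------------------------------------------------------------------
# stage 2
# ----------------------------------------------------------------------

def encode_pooled(bundle: ModelBundle, dataset: LabeledImageSet,
                  batch_size: int = 64) -> np.ndarray:
    """Frozen-encoder features: GAP-pooled encoder output per image."""
    feats = []
    for start in range(0, len(dataset), batch_size):
        batch = np.stack(dataset.images[start:start + batch_size])
        feats.append(global_average_pool(encode(batch, bundle)))
    return np.concatenate(feats, axis=0)


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    n, k = logits.shape
    ones = np.ones((n, k), dtype=logits.data.dtype)
    from .nn import logsumexp

    log_probs = logits - logsumexp(logits, ones, axis=-1)
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    return -(log_probs * onehot).sum() * (1.0 / n)


def _head_forward(bundle: ModelBundle, feats: np.ndarray) -> Tensor:
    return bundle.classifier(bundle.projector(Tensor(feats)))


def train_heads_on_features(bundle: ModelBundle, train_feats: np.ndarray,
                            train_labels: np.ndarray, val_feats: np.ndarray,
                            val_labels: np.ndarray,
                            cfg: TrainConfig) -> tuple[ModelBundle, TrainHistory]:
    """Train projector + classifier on pre-computed pooled features."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3)))
    opt = AdamW(bundle.projector.parameters() + bundle.classifier.parameters(),
                lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state = None
    n = train_feats.shape[0]
    for epoch in range(cfg.max_epochs):
        bundle.projector.train()
        bundle.classifier.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue  # BatchNorm needs at least 2 samples
            logits = _head_forward(bundle, train_feats[idx])
            loss = _cross_entropy(logits, train_labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        bundle.projector.eval()
        bundle.classifier.eval()
        with no_grad():
            val_logits = _head_forward(bundle, val_feats)
            val_loss = _cross_entropy(val_logits, val_labels).item()
        val_acc = float((val_logits.data.argmax(axis=1) == val_labels).mean())
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        stop, best = early_stop(history.val_loss, cfg.patience)
        if best == epoch:
            best_state = (bundle.projector.state_dict(),
                          bundle.classifier.state_dict())
        if stop:
            history.stop_reason = "early_stop"
            break
    else:
        history.stop_reason = "max_epochs"
    history.best_epoch = int(np.argmin(history.val_loss))
    if best_state is not None:
        bundle.projector.load_state_dict(best_state[0])
        bundle.classifier.load_state_dict(best_state[1])
    return bundle, history


def train_heads(bundle: ModelBundle, train_set: LabeledImageSet,
                val_set: LabeledImageSet,
                cfg: TrainConfig) -> tuple[ModelBundle, TrainHistory]:
    """Stage 2: frozen-encoder supervised training of the heads."""
    if not bundle.frozen.get("encoder", False):
        warnings.warn("encoder was not frozen at entry; freezing it now")
    freeze_encoder(bundle)
    before = bundle.encoder_checksum()
    train_feats = encode_pooled(bundle, train_set)
    val_feats = encode_pooled(bundle, val_set)
    bundle, history = train_heads_on_features(
        bundle, train_feats, train_set.labels, val_feats, val_set.labels, cfg)
    assert bundle.encoder_checksum() == before, "frozen encoder changed"
    return bundle, history


def train_sl_baseline(bundle: ModelBundle, train_set: LabeledImageSet,
                      val_set: LabeledImageSet, cfg: TrainConfig,
                      fine_tune: bool = False) -> tuple[ModelBundle, TrainHistory]:
    """Supervised baseline: stage 2 without any contrastive pretraining.

    Default mode freezes the (generically initialized) encoder so the
    baseline differs from the two-stage pipeline only in the pretraining
    objective; ``fine_tune=True`` trains the encoder jointly instead.
    """
    if not fine_tune:
        freeze_encoder(bundle)
        return train_heads(bundle, train_set, val_set, cfg)
    # fine-tune mode: optimize encoder and heads end-to-end
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 4)))
    params = (bundle.encoder.parameters() + bundle.projector.parameters()
              + bundle.classifier.parameters())
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    n = len(train_set)
    for epoch in range(cfg.max_epochs):
        bundle.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue
            batch = np.stack([train_set.images[i] for i in idx])
            tokens = bundle.encoder(batch)
            logits = bundle.classifier(bundle.projector(tokens.mean(axis=1)))
            loss = _cross_entropy(logits, train_set.labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        bundle.eval()
        with no_grad():
            val_feats = encode_pooled(bundle, val_set)
            val_logits = _head_forward(bundle, val_feats)
            val_loss = _cross_entropy(val_logits, val_set.labels).item()
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(
            float((val_logits.data.argmax(axis=1) == val_set.labels).mean()))
        stop, _ = early_stop(history.val_loss, cfg.patience)
        if stop:
            history.stop_reason = "early_stop"
            break
    else:
        history.stop_reason = "max_epochs"
    history.best_epoch = int(np.argmin(history.val_loss))
    return bundle, history
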