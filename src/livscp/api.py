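"""Estimator-style surface: build from data, ``fit()``, get results.

``LivSCP`` runs the full two-stage pipeline (class-weighted contrastive
pretraining, then frozen-encoder head training); ``SLBaseline`` runs only
the supervised stage on a generically initialized encoder.  Both return
a :class:`FitResults` carrying the trained bundle, the per-stage
histories, and evaluation helpers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contrastive import ClassWeights, compute_class_weights
from .datapipe import AugmentationConfig, LabeledImageSet, preprocess
from .evalreport import MetricsReport, evaluate_quantized, predict_proba, compute_metrics
from .model import ModelBundle, ModelConfig, build_model
from .trainer import TrainConfig, TrainHistory, pretrain_scp, train_heads, train_sl_baseline

__all__ = ["FitResults", "LivSCP", "SLBaseline", "load_checkpoint",
           "prepare_dataset", "save_checkpoint"]


def prepare_dataset(dataset: LabeledImageSet, cfg: ModelConfig) -> LabeledImageSet:
    """Resize + Z-standardize every image to the model's input contract."""
    size = (cfg.image_height, cfg.image_width)

    def prep(im):
        out = preprocess(im, size)
        if cfg.channels == 3 and out.ndim == 2:
            out = np.stack([out] * 3, axis=-1)
        if cfg.channels == 1 and out.ndim == 3:
            out = out.mean(axis=-1)
        return out.astype(np.float32)

    return dataset.map_images(prep)


@dataclass
class FitResults:
    """Outcome of a training run: weights, histories, diagnostics."""

    bundle: ModelBundle
    method: str
    pretrain_history: TrainHistory | None
    head_history: TrainHistory
    class_weights: ClassWeights | None
    train_config: TrainConfig

    def evaluate(self, test_set: LabeledImageSet,
                 precision: str = "FP32") -> MetricsReport | list[MetricsReport]:
        """Metrics on a test set; ``precision`` in FP32|FP16|INT8|all."""
        if precision.lower() == "all":
            return evaluate_quantized(self.bundle, test_set)
        from .evalreport import quantize

        qb = quantize(self.bundle, precision)
        probs = predict_proba(qb, test_set)
        return compute_metrics(probs, test_set.labels,
                               precision_level=precision.upper())

    def summary(self) -> str:
        lines = [f"{self.method} fit results", "=" * 32]
        if self.pretrain_history is not None:
            h = self.pretrain_history
            lines += [
                f"stage 1 (contrastive pretrain): {len(h)} epochs "
                f"({h.stop_reason}), best epoch {h.best_epoch + 1}",
                f"  best val contrastive loss: {min(h.val_loss):.4f}",
            ]
        h = self.head_history
        lines += [
            f"stage 2 (head training): {len(h)} epochs "
            f"({h.stop_reason}), best epoch {h.best_epoch + 1}",
            f"  best val loss: {min(h.val_loss):.4f}",
        ]
        if h.val_accuracy:
            lines.append(f"  val accuracy at best epoch: "
                         f"{h.val_accuracy[h.best_epoch]:.4f}")
        return "\n".join(lines)


class LivSCP:
    """Two-stage pipeline: CW-SCL pretraining, then frozen-head training.

    Parameters
    ----------
    train_set, val_set : LabeledImageSet
        Preprocessed images (see :func:`prepare_dataset`).
    model_config : ModelConfig
    pretrain_config, head_config : TrainConfig
        Stage-specific optimization settings; defaults follow the
        published recipe.
    augmentation : AugmentationConfig, optional
        Stage-1 two-view augmentations.
    """

    method = "LivSCP"

    def __init__(self, train_set: LabeledImageSet, val_set: LabeledImageSet,
                 model_config: ModelConfig,
                 pretrain_config: TrainConfig = TrainConfig(),
                 head_config: TrainConfig = TrainConfig(),
                 augmentation: AugmentationConfig | None = None):
        self.train_set = train_set
        self.val_set = val_set
        self.model_config = model_config
        self.pretrain_config = pretrain_config
        self.head_config = head_config
        self.augmentation = augmentation

    def fit(self, seed: int = 0) -> FitResults:
        bundle = build_model(self.model_config, seed=seed)
        weights = compute_class_weights(self.train_set.class_counts)
        pre_cfg = dataclasses.replace(self.pretrain_config, seed=seed,
                                      stage="scp_pretrain")
        bundle, pre_hist = pretrain_scp(bundle, self.train_set, self.val_set,
                                        weights, pre_cfg, aug=self.augmentation)
        head_cfg = dataclasses.replace(self.head_config, seed=seed,
                                       stage="head_train")
        from .model import freeze_encoder

        freeze_encoder(bundle)
        bundle, head_hist = train_heads(bundle, self.train_set, self.val_set,
                                        head_cfg)
        return FitResults(bundle=bundle, method=self.method,
                          pretrain_history=pre_hist, head_history=head_hist,
                          class_weights=weights, train_config=head_cfg)


class SLBaseline:
    """Supervised baseline: same architecture, heads and settings, but no
    contrastive pretraining (frozen generically initialized encoder by
    default; ``fine_tune=True`` trains the encoder jointly)."""

    method = "SL"

    def __init__(self, train_set: LabeledImageSet, val_set: LabeledImageSet,
                 model_config: ModelConfig,
                 head_config: TrainConfig = TrainConfig(),
                 fine_tune: bool = False):
        self.train_set = train_set
        self.val_set = val_set
        self.model_config = model_config
        self.head_config = head_config
        self.fine_tune = fine_tune

    def fit(self, seed: int = 0) -> FitResults:
        bundle = build_model(self.model_config, seed=seed)
        bundle.contrastive_head = None
        cfg = dataclasses.replace(self.head_config, seed=seed,
                                  stage="sl_baseline")
        bundle, hist = train_sl_baseline(bundle, self.train_set, self.val_set,
                                         cfg, fine_tune=self.fine_tune)
        return FitResults(bundle=bundle, method=self.method,
                          pretrain_history=None, head_history=hist,
                          class_weights=None, train_config=cfg)


# ----------------------------------------------------------------------

def save_checkpoint(bundle: ModelBundle, path,
                    history: TrainHistory | None = None) -> None:
    """Persist config + weights (+ history) as a single ``.npz`` file."""
    arrays = {}
    for comp in ("encoder", "projector", "classifier"):
        mod = getattr(bundle, comp)
        for k, v in mod.state_dict().items():
            arrays[f"{comp}/{k}"] = v
    meta = {"config": dataclasses.asdict(bundle.cfg),
            "frozen": bundle.frozen}
    if history is not None:
        meta["history"] = dataclasses.asdict(history)
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(path) -> tuple[ModelBundle, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        cfg = ModelConfig(**meta["config"])
        bundle = build_model(cfg, seed=0)
        bundle.contrastive_head = None
        for comp in ("encoder", "projector", "classifier"):
            mod = getattr(bundle, comp)
            prefix = comp + "/"
            state = {k[len(prefix):]: data[k] for k in data.files
                     if k.startswith(prefix)}
            mod.load_state_dict(state)
    bundle.frozen = meta.get("frozen", {"encoder": False})
    if bundle.frozen.get("encoder"):
        from .model import freeze_encoder

        freeze_encoder(bundle)
    return bundle, meta
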