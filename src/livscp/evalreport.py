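"""Metrics, quantized evaluation, and improvement arithmetic.

The metric suite mirrors the multiclass evaluation convention of the
application: accuracy, support-weighted one-vs-rest precision / recall /
F1 (weighted recall is algebraically identical to accuracy, which the
report asserts), per-class one-vs-rest AUROC with 0.5 credit for ties,
and their unweighted macro mean (mAUROC).  Predictions are the row
argmax with ties broken to the lowest class index.

Quantized evaluation compares the same trained network at three
precision levels: FP32 (identity), FP16 (parameters and linear-layer
activations cast to half precision) and INT8 (dynamic per-tensor affine
quantization of linear layers, the standard CPU post-training path).
"""

from __future__ import annotations

import copy
import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)

from .datapipe import LabeledImageSet
from .model import ModelBundle, classify, encode, pool_project

__all__ = [
    "ImprovementReport",
    "MetricsReport",
    "compute_metrics",
    "evaluate_quantized",
    "export_roc",
    "improvement_report",
    "predict_proba",
    "quantize",
]

PRECISION_LEVELS = ("FP32", "FP16", "INT8")
_METRIC_FIELDS = ("accuracy", "precision", "recall", "f1", "mauroc")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mauroc: float | None = None
    per_class_auroc: np.ndarray | None = None
    roc_curves: dict | None = None
    precision_level: str = "FP32"
    n_samples: int = 0

    def __post_init__(self):
        for name in _METRIC_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.recall - self.accuracy) > 1e-12:
            raise ValueError("weighted recall must equal accuracy")
        if self.per_class_auroc is not None and self.mauroc is not None:
            defined = self.per_class_auroc[~np.isnan(self.per_class_auroc)]
            if abs(self.mauroc - defined.mean()) > 1e-12:
                raise ValueError("mauroc must be the mean of per-class AUROC")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in _METRIC_FIELDS
                if getattr(self, k) is not None}

    def summary(self) -> str:
        lines = [f"MetricsReport [{self.precision_level}] "
                 f"(n={self.n_samples})"]
        for k, v in self.as_dict().items():
            lines.append(f"  {k:<10s} {v:.4f}")
        return "\n".join(lines)


def compute_metrics(probabilities: np.ndarray, labels,
                    precision_level: str = "FP32") -> MetricsReport:
    """Full metric suite from class probabilities.

    ``probabilities`` is an N x K row-stochastic matrix; ``labels`` a
    length-N integer vector.  Classes absent from ``labels`` have
    undefined AUROC and are excluded from the macro mean with a warning.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if p.ndim != 2:
        raise ValueError("probabilities must be an N x K matrix")
    n, k = p.shape
    if y.shape != (n,):
        raise ValueError("labels length must match probabilities rows")
    if n < k:
        raise ValueError("need at least as many samples as classes")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-5):
        raise ValueError("probability rows must sum to 1")
    if np.unique(y).size < 2:
        raise ValueError("AUROC undefined with a single observed class")
    preds = p.argmax(axis=1)  # np argmax: ties -> lowest index
    accuracy = float((preds == y).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, preds, labels=np.arange(k), average="weighted", zero_division=0)
    per_class = np.full(k, np.nan)
    curves = {}
    observed = set(np.unique(y).tolist())
    for c in range(k):
        if c not in observed:
            warnings.warn(f"class {c} absent from labels; AUROC undefined")
            continue
        binary = (y == c).astype(int)
        per_class[c] = roc_auc_score(binary, p[:, c])
        fpr, tpr, thr = roc_curve(binary, p[:, c], drop_intermediate=False)
        curves[c] = (fpr, tpr, thr)
    mauroc = float(np.nanmean(per_class))
    return MetricsReport(accuracy=accuracy, precision=float(prec),
                         recall=float(rec), f1=float(f1), mauroc=mauroc,
                         per_class_auroc=per_class, roc_curves=curves,
                         precision_level=precision_level, n_samples=n)


# ----------------------------------------------------------------------

def quantize(bundle: ModelBundle, mode: str) -> ModelBundle:
    """Return a copy of the bundle set to run inference at ``mode``.

    FP32 is the identity; FP16 and INT8 simulate reduced-precision
    inference inside the linear layers (see module docstring).
    """
    mode = mode.upper()
    if mode not in PRECISION_LEVELS:
        raise ValueError(f"unsupported precision mode: {mode!r}")
    out = copy.deepcopy(bundle)
    out.set_qmode(mode.lower() if mode != "FP32" else "fp32")
    return out


def predict_proba(bundle: ModelBundle, dataset: LabeledImageSet,
                  batch_size: int = 64) -> np.ndarray:
    """Softmax class probabilities over a dataset (eval mode)."""
    bundle.eval()
    probs = []
    for start in range(0, len(dataset), batch_size):
        batch = np.stack(dataset.images[start:start + batch_size])
        f = encode(batch, bundle)
        logits = classify(pool_project(f, bundle), bundle).astype(np.float64)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(probs, axis=0)


def evaluate_quantized(bundle: ModelBundle, test_set: LabeledImageSet,
                       batch_size: int = 64) -> list[MetricsReport]:
    """Evaluate the same model at FP32, FP16 and INT8 on one test set."""
    reports = []
    for level in PRECISION_LEVELS:
        qb = quantize(bundle, level)
        probs = predict_proba(qb, test_set, batch_size=batch_size)
        reports.append(compute_metrics(probs, test_set.labels,
                                       precision_level=level))
    return reports


# ----------------------------------------------------------------------

@dataclass
class ImprovementReport:
    """Absolute metric deltas in percentage points, ``100 * (a - b)``."""

    deltas: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict:
        return {k: round(v, ndigits) for k, v in self.deltas.items()}

    def summary(self) -> str:
        lines = ["ImprovementReport (absolute percentage points)"]
        for k, v in self.rounded().items():
            lines.append(f"  {k:<10s} {v:+.2f}")
        return "\n".join(lines)


def _metric_dict(x) -> dict:
    if isinstance(x, MetricsReport):
        return x.as_dict()
    return {k: float(v) for k, v in dict(x).items()}


def improvement_report(a, b) -> ImprovementReport:
    """Absolute improvement of ``a`` over ``b`` per shared metric.

    Accepts :class:`MetricsReport` objects or plain ``{metric: fraction}``
    mappings; deltas are reported in percentage points.
    """
    da, db = _metric_dict(a), _metric_dict(b)
    deltas = {k: 100.0 * (da[k] - db[k]) for k in da if k in db}
    return ImprovementReport(deltas=deltas)


def export_roc(report: MetricsReport, out_dir) -> list[Path]:
    """Write per-class ROC CSVs and a ROC plot for the report's precision.

    CSV columns are ``fpr,tpr,threshold`` over the full score set (no
    fixed threshold grid); the plot is one PNG with all classes overlaid.
    """
    if report.roc_curves is None:
        raise ValueError("report carries no ROC curves")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for c, (fpr, tpr, thr) in sorted(report.roc_curves.items()):
        path = out_dir / f"roc_class{c}_{report.precision_level.lower()}.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fpr", "tpr", "threshold"])
            for row in zip(fpr, tpr, thr):
                w.writerow([f"{row[0]:.10g}", f"{row[1]:.10g}",
                            f"{row[2]:.10g}"])
        written.append(path)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for c, (fpr, tpr, _) in sorted(report.roc_curves.items()):
        auc = report.per_class_auroc[c] if report.per_class_auroc is not None else np.nan
        ax.plot(fpr, tpr, label=f"class {c} (AUROC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.set_title(f"One-vs-rest ROC ({report.precision_level})")
    ax.legend(fontsize=8)
    plot_path = out_dir / f"roc_{report.precision_level.lower()}.png"
    fig.savefig(plot_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(plot_path)
    return written
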