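"""Supervised contrastive losses and inverse-frequency class weights.

The supervised contrastive loss (SupCon) acts on a batch of unit-norm
embeddings ``z_i`` with labels ``y_i``.  For an anchor ``i``, the positive
set ``P(i)`` holds the other batch indices sharing its label and the
contrast set ``A(i)`` holds every other index.  The per-anchor term is

    L_i = -(1/|P(i)|) * sum_{p in P(i)} log[ exp(z_i.z_p / tau)
                                             / sum_{a in A(i)} exp(z_i.z_a / tau) ]

and the batch loss averages L_i over anchors.  The class-weighted variant
(CW-SCL) multiplies each anchor term by ``w_{y_i} / w_bar`` where ``w_c``
is inversely proportional to the class frequency (normalized so the class
weights average to one) and ``w_bar`` is the batch mean of the per-sample
weights.  Anchors without positives are dropped from the average — their
term is undefined at ``|P(i)| = 0``.

Both losses are implemented twice: a vectorized numpy path (the public
functions below, and a differentiable twin in :func:`supcon_loss_tensor`)
and a literal triple-loop transcription (:func:`supcon_loss_oracle`) kept
deliberately naive as an independent reference for the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, logsumexp

__all__ = [
    "ClassWeights",
    "ContrastiveSets",
    "DegenerateBatchError",
    "EmbeddingBatch",
    "LossConfig",
    "compute_class_weights",
    "contrastive_sets",
    "cw_supcon_loss",
    "supcon_loss",
    "supcon_loss_oracle",
    "supcon_loss_tensor",
]


class DegenerateBatchError(ValueError):
    """Raised when no anchor in the batch has a positive: loss undefined."""


@dataclass(frozen=True)
class LossConfig:
    """Contrastive-loss settings. ``temperature`` is the softmax sharpness
    tau; the published value is 0.07."""

    temperature: float = 0.07

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights w_c with mean exactly 1.

    ``counts[c]`` is the number of training samples of class ``c`` and
    ``weights[c] = (1/counts[c]) / mean_k(1/counts[k])``.
    """

    counts: np.ndarray
    weights: np.ndarray
    num_classes: int

    def __post_init__(self):
        if not np.isclose(self.weights.mean(), 1.0, atol=1e-9):
            raise ValueError("class weights must average to 1")


def compute_class_weights(counts) -> ClassWeights:
    """Inverse-frequency weights, normalized to mean one.

    Parameters
    ----------
    counts : array-like of int
        Per-class sample counts ``n_c``; at least two classes, all >= 1.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need counts for at least 2 classes")
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    counts = counts.astype(np.int64)
    inv = 1.0 / counts
    weights = inv / inv.mean()
    return ClassWeights(counts=counts, weights=weights,
                        num_classes=int(counts.size))


class EmbeddingBatch:
    """A batch of L2-normalized embeddings with integer labels.

    Rows are normalized on construction; a zero row cannot be normalized
    and is rejected.
    """

    def __init__(self, embeddings, labels):
        z = np.asarray(embeddings, dtype=np.float64)
        y = np.asarray(labels)
        if z.ndim != 2 or z.shape[0] < 2:
            raise ValueError("embeddings must be a (B >= 2) x D matrix")
        if y.shape != (z.shape[0],):
            raise ValueError("labels must be a length-B vector")
        if np.any(y < 0):
            raise ValueError("labels must be non-negative integers")
        norms = np.linalg.norm(z, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero embedding row cannot be normalized")
        self.embeddings = z / norms
        self.labels = y.astype(np.int64)

    @property
    def batch_size(self) -> int:
        return self.embeddings.shape[0]


@dataclass(frozen=True)
class ContrastiveSets:
    """Index sets per anchor: ``positives[i] = P(i)``, same label minus
    self; ``contrast[i] = A(i)``, everything minus self."""

    positives: list = field(default_factory=list)
    contrast: list = field(default_factory=list)


def contrastive_sets(labels) -> ContrastiveSets:
    y = np.asarray(labels)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    pos, con = [], []
    for i in range(y.size):
        pos.append([p for p in range(y.size) if p != i and y[p] == y[i]])
        con.append([a for a in range(y.size) if a != i])
    return ContrastiveSets(positives=pos, contrast=con)


def _masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    B = labels.size
    eye = np.eye(B, dtype=bool)
    mask_a = ~eye
    mask_p = (labels[:, None] == labels[None, :]) & ~eye
    return mask_p, mask_a


def _per_anchor_terms(z: np.ndarray, labels: np.ndarray,
                      tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized L_i^sup for every anchor; returns (terms, valid mask)."""
    mask_p, mask_a = _masks(labels)
    sim = (z @ z.T) / tau
    # stabilize the log-sum-exp over A(i) by the per-anchor masked max
    neg = np.where(mask_a, 0.0, -np.inf)
    row_max = (sim + neg).max(axis=1, keepdims=True)
    log_den = np.log((np.exp(sim - row_max) * mask_a).sum(axis=1,
                                                          keepdims=True)) + row_max
    log_prob = sim - log_den
    n_pos = mask_p.sum(axis=1)
    valid = n_pos > 0
    terms = np.zeros(labels.size)
    terms[valid] = -(log_prob * mask_p).sum(axis=1)[valid] / n_pos[valid]
    return terms, valid


def supcon_loss(batch: EmbeddingBatch, cfg: LossConfig = LossConfig()) -> float:
    """Batch-averaged supervised contrastive loss (unweighted)."""
    terms, valid = _per_anchor_terms(batch.embeddings, batch.labels,
                                     cfg.temperature)
    if not valid.any():
        raise DegenerateBatchError("no anchor has a positive sample")
    return float(terms[valid].mean())


def cw_supcon_loss(batch: EmbeddingBatch, weights: ClassWeights,
                   cfg: LossConfig = LossConfig()) -> float:
    """Class-weighted supervised contrastive loss.

    Each valid anchor's term is scaled by ``w_{y_i} / w_bar`` with
    ``w_bar`` the mean of ``w_{y_i}`` over the whole batch, so rescaling
    all class weights by a positive constant leaves the loss unchanged.
    """
    if batch.labels.max() >= weights.num_classes:
        raise ValueError("batch label outside the class-weight range")
    terms, valid = _per_anchor_terms(batch.embeddings, batch.labels,
                                     cfg.temperature)
    if not valid.any():
        raise DegenerateBatchError("no anchor has a positive sample")
    w = weights.weights[batch.labels]
    w_bar = w.mean()
    return float(((w / w_bar) * terms)[valid].mean())


def supcon_loss_oracle(batch: EmbeddingBatch,
                       weights: ClassWeights | None = None,
                       cfg: LossConfig = LossConfig()) -> float:
    """Literal loop transcription of the loss definitions (test oracle).

    No vectorization, no log-domain tricks: every (anchor, positive,
    contrast) triple is visited explicitly.  Used only by the test suite
    as an independent reference.
    """
    z = batch.embeddings
    y = batch.labels
    B = z.shape[0]
    tau = cfg.temperature
    if weights is not None and y.max() >= weights.num_classes:
        raise ValueError("batch label outside the class-weight range")
    sample_w = [1.0] * B if weights is None else [weights.weights[y[i]]
                                                  for i in range(B)]
    w_bar = sum(sample_w) / B
    total = 0.0
    n_valid = 0
    for i in range(B):
        P = [p for p in range(B) if p != i and y[p] == y[i]]
        if not P:
            continue
        n_valid += 1
        inner = 0.0
        for p in P:
            den = 0.0
            for a in range(B):
                if a != i:
                    den += math.exp(float(z[i] @ z[a]) / tau)
            inner += math.log(math.exp(float(z[i] @ z[p]) / tau) / den)
        total += (sample_w[i] / w_bar) * (-inner / len(P))
    if n_valid == 0:
        raise DegenerateBatchError("no anchor has a positive sample")
    return total / n_valid


def supcon_loss_tensor(z: Tensor, labels: np.ndarray, temperature: float,
                       sample_weights: np.ndarray | None = None) -> Tensor:
    """Differentiable twin of the numpy losses for the training loop.

    ``z`` must already be row-normalized (a differentiable normalization
    is part of the caller's graph).  ``sample_weights`` is the per-sample
    ``w_{y_i}`` lookup; ``None`` gives the unweighted loss.
    """
    labels = np.asarray(labels)
    mask_p, mask_a = _masks(labels)
    sim = (z @ z.transpose(1, 0)) * (1.0 / temperature)
    log_den = logsumexp(sim, mask_a.astype(sim.data.dtype), axis=-1)
    log_prob = sim - log_den
    n_pos = mask_p.sum(axis=1)
    valid = n_pos > 0
    if not valid.any():
        raise DegenerateBatchError("no anchor has a positive sample")
    inv_pos = np.where(valid, 1.0 / np.maximum(n_pos, 1), 0.0)
    # -(1/|P(i)|) sum_p log_prob, zero where P(i) is empty
    terms = -(log_prob * mask_p.astype(sim.data.dtype)).sum(axis=1) * inv_pos
    if sample_weights is not None:
        w = np.asarray(sample_weights, dtype=np.float64)
        terms = terms * (w / w.mean()).astype(sim.data.dtype)
    return terms.sum() * (1.0 / float(valid.sum()))
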