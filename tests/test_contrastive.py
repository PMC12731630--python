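"""Supervised contrastive loss, class-weighted variant, class weights."""

import math

import numpy as np
import pytest

from livscp.contrastive import (
    ClassWeights,
    DegenerateBatchError,
    EmbeddingBatch,
    LossConfig,
    compute_class_weights,
    contrastive_sets,
    cw_supcon_loss,
    supcon_loss,
    supcon_loss_oracle,
    supcon_loss_tensor,
)
from livscp.nn import Tensor

from conftest import random_embedding_batch

REF_COUNTS = [2114, 861, 793, 857, 1698]


def _scaled_weights(weights: ClassWeights, k: float) -> ClassWeights:
    """Bypass the mean-1 invariant to probe weight-scale invariance."""
    cw = ClassWeights.__new__(ClassWeights)
    object.__setattr__(cw, "counts", weights.counts)
    object.__setattr__(cw, "weights", weights.weights * k)
    object.__setattr__(cw, "num_classes", weights.num_classes)
    return cw


class TestComputeClassWeights:
    def test_reference_counts_mean_one(self):
        cw = compute_class_weights(REF_COUNTS)
        assert cw.weights.mean() == pytest.approx(1.0, abs=1e-9)

    def test_reference_counts_values(self):
        # frozen from an exact-rational evaluation of the formula
        expected = [0.508500, 1.248511, 1.355571, 1.254339, 0.633079]
        cw = compute_class_weights(REF_COUNTS)
        np.testing.assert_allclose(cw.weights, expected, atol=1e-4)

    def test_uniform_counts_give_unit_weights(self):
        cw = compute_class_weights([10] * 5)
        np.testing.assert_array_equal(cw.weights, np.ones(5))

    def test_inverse_ordering(self):
        cw = compute_class_weights(REF_COUNTS)
        order_counts = np.argsort(cw.counts)
        order_weights = np.argsort(-cw.weights)
        np.testing.assert_array_equal(order_counts, order_weights)

    @pytest.mark.parametrize("bad", [[0, 5], [-1, 3, 4], [7]])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_class_weights(bad)

    def test_random_counts_mean_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = int(rng.integers(2, 10))
            counts = rng.integers(1, 10_000, size=k)
            cw = compute_class_weights(counts)
            assert cw.weights.mean() == pytest.approx(1.0, abs=1e-9)


class TestContrastiveSets:
    def test_definition_example(self):
        s = contrastive_sets([0, 0, 1])
        assert s.positives[0] == [1]
        assert s.positives[2] == []
        assert s.contrast[0] == [1, 2]

    def test_all_same_label(self):
        s = contrastive_sets([0, 0, 0])
        assert all(len(p) == 2 for p in s.positives)

    def test_mixed_labels(self):
        s = contrastive_sets([0, 1, 2, 0, 1])
        assert s.positives[0] == [3]
        assert s.positives[1] == [4]
        assert s.positives[2] == []

    def test_set_relations(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, size=12)
        s = contrastive_sets(y)
        for i in range(12):
            assert i not in s.contrast[i]
            assert len(s.contrast[i]) == 11
            assert set(s.positives[i]) <= set(s.contrast[i])


class TestEmbeddingBatch:
    def test_rows_normalized(self):
        rng = np.random.default_rng(3)
        b = EmbeddingBatch(rng.normal(size=(8, 5)) * 10, rng.integers(0, 2, 8))
        np.testing.assert_allclose(np.linalg.norm(b.embeddings, axis=1), 1.0,
                                   atol=1e-5)

    @pytest.mark.parametrize("z,y", [
        (np.ones((1, 3)), [0]),                    # B < 2
        (np.zeros((2, 3)), [0, 1]),                # zero row
        (np.ones((2, 3)), [0, -1]),                # negative label
        (np.ones((3, 3)), [0, 1]),                 # length mismatch
    ])
    def test_invalid_batches_rejected(self, z, y):
        with pytest.raises(ValueError):
            EmbeddingBatch(z, y)


class TestSupConLoss:
    def test_single_positive_pair_is_zero(self):
        # the lone positive is the whole contrast set: log(1) = 0
        b = EmbeddingBatch(np.random.default_rng(0).normal(size=(2, 4)), [1, 1])
        assert supcon_loss(b, LossConfig(0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_two_pair_axis_aligned_example(self):
        # each anchor term is -log(e / (e + 2)) at tau = 1
        b = EmbeddingBatch([[1, 0], [1, 0], [0, 1], [0, 1]], [0, 0, 1, 1])
        expected = math.log((math.e + 2) / math.e)
        assert supcon_loss(b, LossConfig(1.0)) == pytest.approx(expected,
                                                               abs=1e-10)

    def test_high_temperature_limit(self):
        # softmax flattens over |A(i)| = 3: loss -> log 3
        b = EmbeddingBatch([[1, 0], [1, 0], [0, 1], [0, 1]], [0, 0, 1, 1])
        assert supcon_loss(b, LossConfig(1e4)) == pytest.approx(math.log(3),
                                                               abs=1e-3)

    def test_high_temperature_general_batches(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            batch, _ = random_embedding_batch(rng, min_b=4, max_b=16)
            pos = [np.sum((batch.labels == y) ) - 1 for y in batch.labels]
            valid = [i for i, p in enumerate(pos) if p > 0]
            if not valid:
                continue
            expected = np.mean([math.log(batch.batch_size - 1) for i in valid])
            assert supcon_loss(batch, LossConfig(1e4)) == pytest.approx(
                expected, abs=1e-3)

    def test_degenerate_batch_raises(self):
        b = EmbeddingBatch(np.eye(3), [0, 1, 2])
        with pytest.raises(DegenerateBatchError):
            supcon_loss(b, LossConfig(0.07))

    def test_separation_monotonicity(self):
        """Pushing the two classes apart on the unit circle lowers the loss."""
        losses = []
        for theta in np.linspace(0.0, np.pi / 2, 8)[1:]:
            u = [1.0, 0.0]
            v = [math.cos(theta), math.sin(theta)]
            b = EmbeddingBatch([u, u, v, v], [0, 0, 1, 1])
            losses.append(supcon_loss(b, LossConfig(0.5)))
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestCWSupConLoss:
    def test_uniform_weights_reduce_to_supcon(self):
        rng = np.random.default_rng(5)
        batch, k = random_embedding_batch(rng)
        w = compute_class_weights([7] * k)
        assert cw_supcon_loss(batch, w, LossConfig(0.07)) == supcon_loss(
            batch, LossConfig(0.07))

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1e6])
    def test_weight_scale_invariance(self, scale):
        rng = np.random.default_rng(6)
        batch = EmbeddingBatch(rng.normal(size=(8, 6)), [0, 0, 1, 1, 1, 2, 2, 2])
        w = compute_class_weights([4, 9, 2])
        base = cw_supcon_loss(batch, w, LossConfig(0.07))
        scaled = cw_supcon_loss(batch, _scaled_weights(w, scale),
                                LossConfig(0.07))
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_imbalanced_batch_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        batch = EmbeddingBatch(rng.normal(size=(6, 4)), [0, 0, 1, 1, 1, 1])
        w = compute_class_weights([2, 4])
        vec = cw_supcon_loss(batch, w, LossConfig(0.07))
        assert vec == pytest.approx(supcon_loss_oracle(batch, w,
                                                       LossConfig(0.07)),
                                    abs=1e-6)

    def test_label_out_of_range_rejected(self):
        batch = EmbeddingBatch(np.eye(4), [0, 0, 3, 3])
        w = compute_class_weights([2, 2])
        with pytest.raises(ValueError):
            cw_supcon_loss(batch, w, LossConfig(0.07))


class TestOracleEquivalence:
    def test_vectorized_matches_oracle_on_random_batches(self):
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 100:
            batch, k = random_embedding_batch(rng)
            counts = rng.integers(1, 50, size=k)
            w = compute_class_weights(counts)
            cfg = LossConfig(float(rng.uniform(0.05, 2.0)))
            try:
                expected_plain = supcon_loss_oracle(batch, None, cfg)
            except DegenerateBatchError:
                with pytest.raises(DegenerateBatchError):
                    supcon_loss(batch, cfg)
                continue
            assert supcon_loss(batch, cfg) == pytest.approx(expected_plain,
                                                            abs=1e-6)
            assert cw_supcon_loss(batch, w, cfg) == pytest.approx(
                supcon_loss_oracle(batch, w, cfg), abs=1e-6)
            checked += 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        batch = EmbeddingBatch(rng.normal(size=(10, 8)),
                               rng.integers(0, 3, size=10))
        w = compute_class_weights([3, 5, 2])
        cfg = LossConfig(0.07)
        perm = rng.permutation(10)
        shuffled = EmbeddingBatch(batch.embeddings[perm], batch.labels[perm])
        assert supcon_loss(shuffled, cfg) == pytest.approx(
            supcon_loss(batch, cfg), abs=1e-6)
        assert cw_supcon_loss(shuffled, w, cfg) == pytest.approx(
            cw_supcon_loss(batch, w, cfg), abs=1e-6)

    def test_differentiable_twin_matches_numpy(self):
        rng = np.random.default_rng(10)
        batch = EmbeddingBatch(rng.normal(size=(12, 16)),
                               rng.integers(0, 4, size=12))
        w = compute_class_weights([5, 4, 3, 2])
        z = Tensor(batch.embeddings, requires_grad=True)
        t = supcon_loss_tensor(z, batch.labels, 0.07, w.weights[batch.labels])
        assert t.item() == pytest.approx(
            cw_supcon_loss(batch, w, LossConfig(0.07)), abs=1e-9)
        t.backward()
        assert np.isfinite(z.grad).all()
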