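"""Preprocessing, splitting, augmentation and two-view batch construction."""

import numpy as np
import pytest

import livscp as lv
from livscp.datapipe import (
    AugmentationConfig,
    SplitRatios,
    augment,
    export_split_csv,
    load_dataset,
    preprocess,
    split,
    split_indices,
    two_view_batch,
)
from livscp.synthgen import REFERENCE_COUNTS, SynthParams, generate, write_dataset

TABLE_LABELS = np.repeat(np.arange(5), REFERENCE_COUNTS)


class TestPreprocess:
    def test_output_is_standardized(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(100, 130), dtype=np.uint8)
        out = preprocess(img, (64, 64))
        assert out.shape == (64, 64)
        assert out.mean() == pytest.approx(0.0, abs=1e-5)
        assert out.std() == pytest.approx(1.0, abs=1e-5)

    def test_rgb_input_standardized_jointly(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(50, 60, 3), dtype=np.uint8)
        out = preprocess(img, (32, 32))
        assert out.shape == (32, 32, 3)
        assert out.mean() == pytest.approx(0.0, abs=1e-5)

    def test_constant_image_maps_to_zeros(self):
        out = preprocess(np.full((40, 40), 17, dtype=np.uint8), (16, 16))
        np.testing.assert_array_equal(out, 0.0)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.empty((0, 0)))

    def test_bicubic_preserves_linear_ramp(self):
        # bicubic interpolation reproduces linear functions
        ramp448 = np.tile(np.linspace(0, 255, 448), (448, 1))
        ramp224 = np.tile(np.linspace(0, 255, 224), (224, 1))
        out = preprocess(ramp448, (224, 224))
        ref = preprocess(ramp224, (224, 224))
        assert np.abs(out - ref).max() < 1e-3


class TestSplit:
    def test_global_floor_mode_on_full_scale_counts(self):
        tr, va, te = split_indices(TABLE_LABELS, SplitRatios(), seed=0,
                                   stratified=False)
        assert len(tr) == 5058
        assert len(tr) + len(va) + len(te) == 6323

    def test_stratified_mode_on_full_scale_counts(self):
        tr, _, _ = split_indices(TABLE_LABELS, SplitRatios(), seed=0,
                                 stratified=True)
        assert len(tr) == sum(int(0.8 * c) for c in REFERENCE_COUNTS) == 5056

    def test_two_class_example(self):
        labels = np.repeat([0, 1], 10)
        tr, va, te = split_indices(labels, SplitRatios(), seed=1)
        assert (len(tr), len(va), len(te)) == (16, 2, 2)
        assert np.bincount(labels[tr]).tolist() == [8, 8]

    def test_same_seed_identical_partitions(self):
        labels = np.random.default_rng(2).integers(0, 4, size=200)
        a = split_indices(labels, seed=7)
        b = split_indices(labels, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_partitions_disjoint_exhaustive_stratified(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            counts = rng.integers(5, 80, size=k)
            labels = np.repeat(np.arange(k), counts)
            tr, va, te = split_indices(labels, seed=int(rng.integers(1e6)))
            allidx = np.concatenate([tr, va, te])
            assert len(np.unique(allidx)) == labels.size  # disjoint+exhaustive
            # independent counting oracle: per-class floor sizes
            for c in range(k):
                n_c = counts[c]
                assert (labels[tr] == c).sum() == int(np.floor(0.8 * n_c))
                assert (labels[va] == c).sum() == int(np.floor(0.1 * n_c))

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitRatios(0.8, 0.1, 0.2)

    def test_split_csv_roundtrip(self, tmp_path):
        ds = lv.default_fixture("small")
        parts = split_indices(ds.labels, seed=0)
        path = tmp_path / "split.csv"
        export_split_csv(ds, parts, path)
        rows = path.read_text().strip().splitlines()
        assert len(rows) == len(ds) + 1
        assert rows[0] == "index,label,partition"


class TestAugment:
    def test_all_flags_off_is_identity(self):
        img = np.random.default_rng(0).random((16, 16))
        np.testing.assert_array_equal(
            augment(img, AugmentationConfig.none(), seed=3), img)

    def test_shape_and_dtype_preserved(self):
        rng = np.random.default_rng(1)
        cfg = AugmentationConfig()
        for shape in [(16, 16), (16, 16, 3)]:
            img8 = rng.integers(0, 256, size=shape, dtype=np.uint8)
            out = augment(img8, cfg, seed=5)
            assert out.shape == img8.shape and out.dtype == img8.dtype

    def test_hflip_is_involution(self):
        # seed 2 fires the single enabled coin flip (first uniform < 0.5)
        cfg = AugmentationConfig(rot90=False, hflip=True, vflip=False,
                                 jitter=0.0, blur_sigma=(0.0, 0.0),
                                 noise_std=0.0)
        img = np.random.default_rng(4).random((8, 8))
        once = augment(img, cfg, seed=2)
        assert not np.array_equal(once, img)
        np.testing.assert_array_equal(augment(once, cfg, seed=2), img)

    def test_rot180_equals_double_flip(self):
        img = np.random.default_rng(5).random((8, 8))
        np.testing.assert_array_equal(np.rot90(img, 2), img[::-1, ::-1])

    def test_noise_std_recovered(self):
        cfg = AugmentationConfig(rot90=False, hflip=False, vflip=False,
                                 jitter=0.0, blur_sigma=(0.0, 0.0),
                                 noise_std=0.05, noise_prob=1.0)
        img = np.full((256, 256), 0.5)
        out = augment(img, cfg, seed=1)
        assert (out - img).std() == pytest.approx(0.05, rel=0.1)

    def test_seeded_determinism(self):
        img = np.random.default_rng(6).random((16, 16))
        cfg = AugmentationConfig()
        np.testing.assert_array_equal(augment(img, cfg, seed=9),
                                      augment(img, cfg, seed=9))


@pytest.fixture(scope="module")
def dataset():
    params = SynthParams(num_classes=3, class_counts=[6, 4, 4],
                         image_size=16, seed=3)
    return generate(params)


class TestTwoViewBatch:
    def test_pairing_and_labels(self, dataset):
        views, labels = two_view_batch(dataset, 4, AugmentationConfig(), seed=0)
        assert views.shape[0] == 8 and labels.shape == (8,)
        counts = np.bincount(labels)
        assert (counts % 2 == 0).all()

    def test_every_anchor_has_a_positive(self, dataset):
        from livscp.contrastive import contrastive_sets

        _, labels = two_view_batch(dataset, 5, AugmentationConfig(), seed=1)
        sets = contrastive_sets(labels)
        assert all(len(p) >= 1 for p in sets.positives)

    def test_same_seed_identical_batches(self, dataset):
        v1, l1 = two_view_batch(dataset, 4, AugmentationConfig(), seed=2)
        v2, l2 = two_view_batch(dataset, 4, AugmentationConfig(), seed=2)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(l1, l2)

    def test_oversized_batch_warns_and_samples_with_replacement(self, dataset):
        with pytest.warns(UserWarning):
            views, _ = two_view_batch(dataset, 50, AugmentationConfig(), seed=0)
        assert views.shape[0] == 100


class TestLoadDataset:
    @pytest.fixture()
    def tree(self, tmp_path):
        params = SynthParams(num_classes=5, class_counts=[4, 2, 2, 2, 3],
                             image_size=16, seed=1)
        # 13 images is below the 3-per-class splitting floor; the split
        # test below tops the tree up itself

        write_dataset(generate(params), tmp_path)
        return tmp_path

    def test_counts_from_directory_tree(self, tree):
        ds = load_dataset(tree)
        assert ds.class_counts.tolist() == [4, 2, 2, 2, 3]
        assert ds.class_names == ["F0", "F1", "F2", "F3", "F4"]

    def test_corrupt_file_skipped_with_warning(self, tree):
        (tree / "F0" / "broken.png").write_bytes(b"not a png")
        with pytest.warns(UserWarning, match="undecodable"):
            ds = load_dataset(tree)
        assert ds.class_counts.tolist() == [4, 2, 2, 2, 3]

    def test_empty_class_excluded_with_warning(self, tree):
        (tree / "F5").mkdir()
        with pytest.warns(UserWarning, match="empty class"):
            ds = load_dataset(tree)
        assert ds.num_classes == 5

    def test_no_classes_is_error(self, tmp_path):
        with pytest.raises(ValueError):
            load_dataset(tmp_path)

    def test_split_of_loaded_dataset(self, tmp_path):
        params = SynthParams(num_classes=5, class_counts=[6, 3, 3, 3, 4],
                             image_size=16, seed=2)
        write_dataset(generate(params), tmp_path)
        ds = load_dataset(tmp_path)
        tr, va, te = split(ds, seed=0)
        assert len(tr) + len(va) + len(te) == len(ds)

    def test_too_small_dataset_split_rejected(self, tree):
        with pytest.raises(ValueError, match="too small"):
            split(load_dataset(tree), seed=0)
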