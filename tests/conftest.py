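import numpy as np
import pytest

import livscp as lv


@pytest.fixture(scope="session")
def tiny_cfg():
    return lv.ModelConfig.tiny()


@pytest.fixture(scope="session")
def small_sets(tiny_cfg):
    """Small synthetic fixture, preprocessed and split 8:1:1."""
    ds = lv.default_fixture("small")
    prep = lv.prepare_dataset(ds, tiny_cfg)
    return lv.split(prep, seed=0)


@pytest.fixture(scope="session")
def toy_results(tiny_cfg, small_sets):
    """A quick LivSCP fit on the small fixture, reused by report tests."""
    train, val, _ = small_sets
    pre = lv.TrainConfig(max_epochs=3, batch_size=16)
    head = lv.TrainConfig(max_epochs=10, batch_size=16)
    return lv.LivSCP(train, val, tiny_cfg, pre, head).fit(seed=0)


def random_embedding_batch(rng, min_b=2, max_b=32, max_k=5, max_d=64):
    """Random batch helper shared by oracle-equivalence tests."""
    b = int(rng.integers(min_b, max_b + 1))
    k = int(rng.integers(2, max_k + 1))
    d = int(rng.integers(2, max_d + 1))
    z = rng.normal(size=(b, d))
    y = rng.integers(0, k, size=b)
    return lv.EmbeddingBatch(z, y), k
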