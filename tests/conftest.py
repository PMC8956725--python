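import numpy as np
import pytest

from inferatlas import EmbeddingModel, SyntheticConfig, generate_corpus, train_skipgram


@pytest.fixture(scope="session")
def sim_corpus():
    """Default-condition synthetic corpus shared across the suite."""
    return generate_corpus(SyntheticConfig(n_posts=1000, seed=7))


@pytest.fixture(scope="session")
def sim_pool(sim_corpus):
    return sim_corpus[0]


@pytest.fixture(scope="session")
def sim_truth(sim_corpus):
    return sim_corpus[1]


@pytest.fixture(scope="session")
def sg_model(sim_pool):
    """Skip-gram model over the shared corpus (reduced dimension for speed)."""
    return train_skipgram(
        sim_pool, dim=100, window=5, min_count=5, epochs=5, seed=7
    )


def toy_model(vectors: dict[str, list[float]]) -> EmbeddingModel:
    """Embedding model with hand-set vectors, for geometric oracles."""
    vocab = {t: i for i, t in enumerate(vectors)}
    mat = np.array([vectors[t] for t in vocab], dtype=np.float32)
    return EmbeddingModel(
        vocabulary=vocab,
        vectors=mat,
        dim=mat.shape[1],
        window=2,
        min_count=1,
        seed=0,
    )
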