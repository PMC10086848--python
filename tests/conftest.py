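import numpy as np
import pytest

from specbias import BipolarAttribute, EmbeddingModel, Lexicon


@pytest.fixture
def toy_model() -> EmbeddingModel:
    """Tiny 3-d model with hand-checkable geometry."""
    return EmbeddingModel.from_pairs(
        "toy",
        [
            ("cat", (1.0, 0.0, 0.0)),
            ("dog", (0.0, 1.0, 0.0)),
            ("fish", (0.6, 0.8, 0.0)),
            ("bird", (0.0, 0.0, 1.0)),
            ("good", (1.0, 0.0, 0.0)),
            ("bad", (0.0, 1.0, 0.0)),
        ],
    )


@pytest.fixture
def toy_attribute() -> BipolarAttribute:
    return BipolarAttribute(
        "toy_attr", Lexicon("pos", ("good",)), Lexicon("neg", ("bad",))
    )


def random_model(rng: np.random.Generator, n_words: int = 20, dim: int = 10, name: str = "rand") -> EmbeddingModel:
    """Random small model for oracle comparisons (no zero vectors)."""
    mat = rng.standard_normal((n_words, dim))
    return EmbeddingModel.from_pairs(name, [(f"w{i}", mat[i]) for i in range(n_words)])
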