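import numpy as np
import pytest

from erandet.corpus_io import Vocabulary


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_vocab():
    """Six real tokens with deterministic 4-d embeddings; PAD row is zero."""
    tokens = ["i", "feel", "sad", "happy", "the", "day"]
    rng = np.random.default_rng(7)
    emb = rng.normal(size=(len(tokens) + 2, 4))
    emb[0] = 0.0
    return Vocabulary(tokens, emb)
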