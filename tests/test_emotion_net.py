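"""TextCNN mechanics, pretraining behaviour and the emotion expectation."""

import numpy as np
import pytest

from erandet.corpus_io import build_vocabulary
from erandet.emotion_net import (
    EmotionNetConfig,
    TextCnnParams,
    conv_feature,
    emotion_vectors,
    max_over_time,
    pretrain_emotion_classifier,
    textcnn_forward,
    textcnn_hidden,
    user_emotion_expectation,
)
from erandet.synthetic_data import GeneratorConfig, generate_emotion_corpus

SMALL_CFG = EmotionNetConfig(filter_heights=(2, 3), n_filters=8, hidden_dim=8,
                             post_len=10, max_epochs=60, batch_size=32,
                             patience=8, lr=2e-3)


@pytest.fixture(scope="module")
def pretrained():
    cfg = GeneratorConfig(n_emotion_posts=300, noise_rate=0.05, seed=9)
    corpus = generate_emotion_corpus(cfg)
    held_cfg = GeneratorConfig(n_emotion_posts=120, noise_rate=0.05, seed=10)
    held_out = generate_emotion_corpus(held_cfg)
    texts = [t for t, _ in corpus.records] + [t for t, _ in held_out.records]
    vocab = build_vocabulary(texts, d=16, seed=0)
    params = pretrain_emotion_classifier(corpus, vocab, SMALL_CFG, seed=4)
    return corpus, held_out, vocab, params


class TestConvFeature:
    def test_zero_filter_zero_bias_relu(self):
        window = np.ones((2, 3))
        assert conv_feature(window, np.zeros((2, 3)), 0.0) == 0.0

    def test_hand_computed_dot_product(self):
        # 2x2 constant window, identity-like filter: sum = h*d*const*w
        window = np.full((2, 2), 3.0)
        filt = np.full((2, 2), 0.5)
        assert conv_feature(window, filt, 0.0) == pytest.approx(2 * 2 * 3.0 * 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conv_feature(np.ones((2, 3)), np.ones((3, 3)), 0.0)

    @pytest.mark.parametrize("h", [2, 3])
    def test_feature_map_length(self, tiny_vocab, h):
        """Sliding a height-h filter over an n-token post gives n-h+1 features."""
        cfg = EmotionNetConfig(filter_heights=(2, 3), n_filters=4, hidden_dim=4,
                               post_len=8)
        params = TextCnnParams(tiny_vocab, cfg, seed=0)
        from erandet.emotion_net import _conv_bank
        from erandet.nn import Tensor
        ids = np.array([[2, 3, 4, 5, 2, 3, 4, 5]])
        emb = params.embedding[ids]
        fmap = _conv_bank(emb, params.filters[h], params.filter_bias[h], h)
        assert fmap.shape == (1, 8 - h + 1, 4)


class TestMaxOverTime:
    def test_picks_maximum(self):
        assert max_over_time([0.1, 0.9, 0.3]) == 0.9

    def test_constant_map(self):
        assert max_over_time([0.4] * 7) == 0.4

    def test_shuffle_invariance(self, rng):
        m = rng.normal(size=20)
        assert max_over_time(m) == max_over_time(rng.permutation(m))

    def test_empty_map_rejected_with_padding_hint(self):
        with pytest.raises(ValueError, match="pad"):
            max_over_time(np.array([]))

    def test_pooled_vector_length_is_heights_times_filters(self, tiny_vocab):
        cfg = EmotionNetConfig(filter_heights=(2, 3, 4), n_filters=4,
                               hidden_dim=6, post_len=8)
        params = TextCnnParams(tiny_vocab, cfg, seed=0)
        assert params.fc.W.shape[0] == 3 * 4


class TestForward:
    def test_all_pad_with_zero_biases_gives_zero_hidden(self, tiny_vocab):
        cfg = EmotionNetConfig(filter_heights=(2,), n_filters=4, hidden_dim=5,
                               post_len=6)
        params = TextCnnParams(tiny_vocab, cfg, seed=0)
        params.fc.b.data[:] = 0.0  # biases are zero-initialized; make explicit
        probs, hidden = textcnn_forward(np.zeros(6, dtype=np.int64), params)
        assert np.allclose(hidden, 0.0)

    def test_sigmoid_head_probabilities_in_unit_interval(self, tiny_vocab):
        cfg = EmotionNetConfig(filter_heights=(2, 3), n_filters=4, hidden_dim=5,
                               post_len=6)
        params = TextCnnParams(tiny_vocab, cfg, seed=1)
        probs, _ = textcnn_forward(np.array([2, 3, 4, 5, 0, 0]), params)
        assert probs.shape == (3,)
        assert np.all((probs > 0) & (probs < 1))

    def test_too_short_post_rejected(self, tiny_vocab):
        cfg = EmotionNetConfig(filter_heights=(3,), n_filters=2, hidden_dim=2,
                               post_len=3)
        params = TextCnnParams(tiny_vocab, cfg, seed=0)
        with pytest.raises(ValueError, match="filter height"):
            textcnn_hidden(np.array([2, 3]), params)


class TestPretraining:
    def test_heldout_accuracy_on_separable_corpus(self, pretrained):
        corpus, held_out, vocab, params = pretrained
        from erandet.corpus_io import tokenize_and_pad
        X = np.stack([tokenize_and_pad(t, vocab, SMALL_CFG.post_len)
                      for t, _ in held_out.records])
        labels = {"positive": 0, "negative": 1, "neutral": 2}
        y = np.array([labels[l] for _, l in held_out.records])
        probs, _ = textcnn_forward(X, params)
        assert (probs.argmax(axis=1) == y).mean() >= 0.95

    def test_training_is_deterministic_given_seed(self, pretrained):
        corpus, _, vocab, params = pretrained
        again = pretrain_emotion_classifier(corpus, vocab, SMALL_CFG, seed=4)
        for k, v in params.state_arrays().items():
            assert np.array_equal(v, again.state_arrays()[k]), k

    def test_missing_class_rejected(self, pretrained):
        from erandet.corpus_io import EmotionCorpus
        corpus = EmotionCorpus([("happy nice", "positive"), ("sad bad", "negative"),
                                ("great fun", "positive")])
        _, _, vocab, _ = pretrained
        with pytest.raises(ValueError):
            pretrain_emotion_classifier(corpus, vocab, SMALL_CFG, seed=0)

    def test_train_loss_trends_down(self, pretrained):
        corpus, _, vocab, _ = pretrained
        cfg = EmotionNetConfig(filter_heights=(2, 3), n_filters=4, hidden_dim=8,
                               post_len=10, max_epochs=8, batch_size=32,
                               patience=8, lr=5e-4)
        _, history = pretrain_emotion_classifier(corpus, vocab, cfg, seed=2,
                                                 return_history=True)
        train_losses = [h[0] for h in history]
        assert train_losses[-1] < train_losses[0]


class TestEmotionExpectation:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(user_emotion_expectation(np.stack([v] * 5)), v)

    def test_two_basis_vectors(self):
        vecs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(user_emotion_expectation(vecs), [0.5, 0.5])

    def test_matches_naive_summation(self, rng):
        vecs = rng.normal(size=(10, 7))
        naive = sum(vecs[i] for i in range(10)) / 10.0
        assert np.allclose(user_emotion_expectation(vecs), naive, atol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            user_emotion_expectation(np.empty((0, 3)))
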