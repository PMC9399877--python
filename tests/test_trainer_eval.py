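"""Metrics, splits, training schedule behaviour, ablation wiring and the
attention dump."""

import numpy as np
import pytest

from erandet.corpus_io import build_vocabulary
from erandet.emotion_net import EmotionNetConfig, pretrain_emotion_classifier
from erandet.synthetic_data import GeneratorConfig, generate_emotion_corpus, generate_user_histories
from erandet.trainer_eval import (
    EranModel,
    EvalReport,
    TrainConfig,
    evaluate,
    export_attention_viz,
    f1_score,
    materialize_subsets,
    prepare_users,
    split_dataset,
    train,
)


class TestEvalReport:
    def test_perfect_predictions(self):
        rep = EvalReport.from_predictions([1, 0, 1, 0], [1, 0, 1, 0])
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_f1_identity_on_random_confusions(self, rng):
        for _ in range(50):
            rep = EvalReport(*(int(k) for k in rng.integers(0, 30, size=4)))
            p, r = rep.precision, rep.recall
            if p + r > 0:
                assert abs(rep.f1 - 2 * p * r / (p + r)) < 1e-9
            total = rep.tp + rep.fp + rep.fn + rep.tn
            assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / total)

    def test_agrees_with_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        y_true = rng.integers(0, 2, size=60)
        y_pred = rng.integers(0, 2, size=60)
        rep = EvalReport.from_predictions(y_true, y_pred)
        assert rep.precision == pytest.approx(
            sk.precision_score(y_true, y_pred, zero_division=0))
        assert rep.recall == pytest.approx(sk.recall_score(y_true, y_pred))
        assert rep.f1 == pytest.approx(sk.f1_score(y_true, y_pred))

    def test_zero_predicted_positives_warns(self):
        rep = EvalReport.from_predictions([1, 1, 0], [0, 0, 0])
        with pytest.warns(UserWarning):
            assert rep.precision == 0.0


class TestSplit:
    def test_stratified_proportions(self):
        gen = GeneratorConfig(n_users=60, posts_per_user=(15, 16), seed=0)
        histories, _ = generate_user_histories(gen)
        vocab = build_vocabulary([p.text for h in histories for p in h.posts], 8, 0)
        users = prepare_users(histories, vocab, 6, None)
        tr, dev, te = split_dataset(users, seed=3)
        assert len(tr) + len(dev) + len(te) == 60
        assert len(te) == 12
        for part in (tr, dev, te):
            labels = [u.label for u in part]
            assert abs(sum(labels) - len(labels) / 2) <= 1

    def test_partitions_are_disjoint(self):
        gen = GeneratorConfig(n_users=20, posts_per_user=(15, 16), seed=1)
        histories, _ = generate_user_histories(gen)
        vocab = build_vocabulary([p.text for h in histories for p in h.posts], 8, 0)
        users = prepare_users(histories, vocab, 6, None)
        tr, dev, te = split_dataset(users, seed=5)
        ids = [u.user_id for u in tr + dev + te]
        assert len(ids) == len(set(ids))


@pytest.fixture(scope="module")
def small_run():
    """A fast end-to-end training run shared by the schedule tests."""
    gen = GeneratorConfig(n_users=24, posts_per_user=(15, 15),
                          indicator_fraction=0.15, noise_rate=0.05, seed=2)
    corpus = generate_emotion_corpus(gen)
    histories, truth = generate_user_histories(gen)
    cfg = TrainConfig(embedding_dim=16, bilstm_hidden=8, batch_size=8,
                      post_len=10, policy_hidden=16, warmup_epochs=3, epochs=3)
    emo_cfg = EmotionNetConfig(filter_heights=(2, 3), n_filters=8, hidden_dim=8,
                               post_len=10, max_epochs=20, patience=3)
    texts = [p.text for h in histories for p in h.posts] + [t for t, _ in corpus.records]
    vocab = build_vocabulary(texts, cfg.embedding_dim, seed=0)
    emo = pretrain_emotion_classifier(corpus, vocab, emo_cfg, seed=0)
    users = prepare_users(histories, vocab, cfg.post_len, emo)
    tr, dev, te = split_dataset(users, seed=2)
    log: list[dict] = []
    model = train(tr, dev, vocab, cfg, seed=2, emotion_params=emo, log=log)
    return dict(cfg=cfg, emo=emo, vocab=vocab, users=users, tr=tr, dev=dev,
                te=te, model=model, log=log, truth=truth)


class TestTraining:
    def test_warmup_loss_decreases(self, small_run):
        warm = [e["loss_2"] for e in small_run["log"] if e["phase"] == "warmup"]
        assert warm[-1] < warm[0]

    def test_same_seed_reproduces_metrics_exactly(self, small_run):
        model2 = train(small_run["tr"], small_run["dev"], small_run["vocab"],
                       small_run["cfg"], seed=2, emotion_params=small_run["emo"])
        r1 = evaluate(small_run["model"], small_run["te"])
        r2 = evaluate(model2, small_run["te"])
        assert r1.as_dict() == r2.as_dict()
        for k, v in small_run["model"].state_arrays().items():
            assert np.array_equal(v, model2.state_arrays()[k]), k

    def test_emotion_net_frozen_during_training(self, small_run):
        """Main-model training must never touch the pretrained emotion net."""
        emo = small_run["emo"]
        h_before = emo.param_hash()
        train(small_run["tr"], small_run["dev"], small_run["vocab"],
              small_run["cfg"], seed=3, emotion_params=emo)
        assert emo.param_hash() == h_before

    def test_single_class_dataset_rejected(self, small_run):
        ones = [u for u in small_run["tr"] if u.label == 1]
        with pytest.raises(ValueError):
            train(ones, small_run["dev"], small_run["vocab"], small_run["cfg"],
                  seed=0, emotion_params=small_run["emo"])

    def test_subsets_partition_each_user(self, small_run):
        subs = materialize_subsets(small_run["model"], small_run["te"])
        dep = {u.user_id: set(u.texts) for u in subs["dep"]}
        non = {u.user_id: set(u.texts) for u in subs["non"]}
        for u in subs["orig"]:
            got = dep.get(u.user_id, set()) | non.get(u.user_id, set())
            assert got == set(u.texts)
            assert not dep.get(u.user_id, set()) & non.get(u.user_id, set())


class TestAblationWiring:
    def test_no_rl_variant_selects_every_post(self, small_run):
        cfg = TrainConfig(**{**small_run["cfg"].__dict__, "no_rl": True})
        model = EranModel(small_run["vocab"], cfg, 0, small_run["emo"])
        user = small_run["te"][0]
        dep, non = model.greedy_selection(user)
        assert dep == list(range(user.T)) and non == []

    def test_no_emotion_variant_shrinks_fused_dimension(self, small_run):
        base = small_run["model"]
        cfg = TrainConfig(**{**small_run["cfg"].__dict__, "no_emotion": True})
        model = EranModel(small_run["vocab"], cfg, 0, None)
        d_e = small_run["emo"].config.hidden_dim
        assert (base.classifier.out.W.shape[0]
                - model.classifier.out.W.shape[0]) == d_e

    def test_state_ablation_shrinks_policy_state(self, small_run):
        cfg = TrainConfig(**{**small_run["cfg"].__dict__, "no_emotion_in_state": True})
        model = EranModel(small_run["vocab"], cfg, 0, small_run["emo"])
        d_e = small_run["emo"].config.hidden_dim
        assert small_run["model"].policy.state_dim - model.policy.state_dim == d_e

    def test_conflicting_ablations_rejected(self, small_run):
        cfg = TrainConfig(**{**small_run["cfg"].__dict__,
                             "no_emotion": True, "no_emotion_in_state": True})
        with pytest.raises(ValueError):
            cfg.validate()


class TestAttentionViz:
    def test_tsv_weights_sum_to_one_and_preserve_order(self, small_run, tmp_path):
        tsv = tmp_path / "attn.tsv"
        rows = export_attention_viz(small_run["model"], small_run["te"], tsv)
        lines = tsv.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["user_id", "post_index", "attention_weight", "text"]
        for uid, items in rows.items():
            if items:
                assert sum(w for _, w, _ in items) == pytest.approx(1.0, abs=1e-6)
                assert [t for t, _, _ in items] == sorted(t for t, _, _ in items)

    def test_html_export_written(self, small_run, tmp_path):
        html = tmp_path / "attn.html"
        export_attention_viz(small_run["model"], small_run["te"][:2],
                             tmp_path / "a.tsv", html)
        assert html.read_text().startswith("<html>")


def test_f1_score_closed_form():
    assert f1_score(0.0, 0.0) == 0.0
    assert f1_score(1.0, 1.0) == 1.0
    assert f1_score(0.5, 1.0) == pytest.approx(2 / 3)
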