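"""Benchmark experiments on synthetic data.

These are the package's reference experiments: selection recovery (can the
trained policy find the planted indicator posts?), the REINFORCE estimator
check against exhaustive episode enumeration, the selected/unselected
subset probe, and the ablation table.  They are shared by the test suite
and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import synthetic_data, trainer_eval
from .corpus_io import Vocabulary, build_vocabulary
from .emotion_net import EmotionNetConfig, TextCnnParams, pretrain_emotion_classifier
from .rl_selector import (
    Episode,
    PolicyParams,
    reinforce_gradient,
    sample_episodes,
)
from .synthetic_data import GeneratorConfig, GroundTruth, indicator_recall
from .trainer_eval import (
    EranModel,
    EvalReport,
    TrainConfig,
    benchmark_config,
    evaluate,
    prepare_users,
    split_dataset,
    subset_experiment,
    train,
    train_bilstm_baseline,
)

# Study conditions for the selection-recovery benchmark: 200 users with 20
# posts each, 15% planted indicator posts, 5% lexical noise.
RECOVERY_GENERATOR = dict(n_users=200, posts_per_user=(20, 20),
                          indicator_fraction=0.15, noise_rate=0.05, seed=13)


@dataclass
class Workbench:
    """A generated dataset plus everything needed to train on it."""

    histories: list
    truth: GroundTruth
    vocab: Vocabulary
    emotion_params: TextCnnParams
    config: TrainConfig
    emotion_config: EmotionNetConfig


def make_workbench(gen_cfg: GeneratorConfig, seed: int) -> Workbench:
    """Generate data, build the vocabulary, pretrain the emotion net."""
    config, emo_cfg = benchmark_config()
    corpus = synthetic_data.generate_emotion_corpus(gen_cfg)
    histories, truth = synthetic_data.generate_user_histories(gen_cfg)
    texts = [p.text for h in histories for p in h.posts] + [t for t, _ in corpus.records]
    vocab = build_vocabulary(texts, config.embedding_dim, seed=seed)
    emotion_params = pretrain_emotion_classifier(corpus, vocab, emo_cfg, seed)
    return Workbench(histories, truth, vocab, emotion_params, config, emo_cfg)


# --------------------------------------------------------------------------
# selection recovery + null control
# --------------------------------------------------------------------------

def selection_recovery(seed: int, gen_overrides: dict | None = None) -> dict:
    """Train the full model on the recovery benchmark and measure test F1 and
    micro recall of the planted indicator posts; also run the null control
    (an untrained selector shows no selected/unselected performance gap)."""
    gen_kw = dict(RECOVERY_GENERATOR)
    gen_kw.update(gen_overrides or {})
    wb = make_workbench(GeneratorConfig(**gen_kw), seed)
    users = prepare_users(wb.histories, wb.vocab, wb.config.post_len, wb.emotion_params)
    tr, dev, te = split_dataset(users, seed)
    model = train(tr, dev, wb.vocab, wb.config, seed, wb.emotion_params)
    report = evaluate(model, te)
    _, selections = model.predict(te)
    recall = indicator_recall(selections, wb.truth)

    null = null_control(wb, tr + dev, te, seed)
    return {
        "test_f1": report.f1,
        "test_accuracy": report.accuracy,
        "indicator_recall": recall,
        "null_dep_f1": null["dep"],
        "null_non_f1": null["non"],
        "model": model,
        "workbench": wb,
        "splits": (tr, dev, te),
    }


def null_control(wb: Workbench, train_users, test_users, seed: int,
                 n_probe_seeds: int = 5) -> dict[str, float]:
    """Probe F1 on the subsets produced by an *untrained* selector, whose
    actions are sampled from its near-uniform policy.  Selected and
    unselected halves are then exchangeable, so their probe F1s should agree
    up to probe-training noise; medians over a few probe seeds are reported."""
    null_model = EranModel(wb.vocab, wb.config, seed + 1, wb.emotion_params)
    rng = np.random.default_rng(seed + 31)
    tr_sub = trainer_eval.materialize_subsets(null_model, train_users, sample_rng=rng)
    te_sub = trainer_eval.materialize_subsets(null_model, test_users, sample_rng=rng)
    f1s: dict[str, list[float]] = {"dep": [], "non": []}
    for k in range(n_probe_seeds):
        for name in ("dep", "non"):
            rep = train_bilstm_baseline(
                tr_sub[name], te_sub[name], wb.vocab, seed + 500 + k,
                post_len=null_model.config.post_len)
            f1s[name].append(rep.f1)
    return {name: float(np.median(v)) for name, v in f1s.items()}


def subset_ordering(seed: int, n_probe_seeds: int = 5,
                    recovery: dict | None = None) -> dict:
    """Train the BiLSTM probe on H^dep / H^orig / H^non with several seeds
    and report median F1 per subset (reuses a trained selector)."""
    if recovery is None:
        recovery = selection_recovery(seed)
    model: EranModel = recovery["model"]
    wb: Workbench = recovery["workbench"]
    tr, dev, te = recovery["splits"]
    tr_sub = trainer_eval.materialize_subsets(model, tr + dev)
    te_sub = trainer_eval.materialize_subsets(model, te)
    f1s: dict[str, list[float]] = {"dep": [], "non": [], "orig": []}
    for k in range(n_probe_seeds):
        for name in ("dep", "non", "orig"):
            rep = train_bilstm_baseline(
                tr_sub[name], te_sub[name], wb.vocab, seed + 1000 + k,
                post_len=model.config.post_len)
            f1s[name].append(rep.f1)
    return {name: float(np.median(v)) for name, v in f1s.items()} | {"per_seed": f1s}


# --------------------------------------------------------------------------
# ablation direction
# --------------------------------------------------------------------------

def ablation_direction(seed: int, n_seeds: int = 5, n_users: int = 100,
                       variants=("ERAN", "EBAtt", "RLAtt", "ERN")) -> dict:
    """Median test F1 over several seeds for the full model and its
    ablations, on emotion-signal-bearing synthetic data."""
    # Indicator posts are drawn from the *negative-emotion* lexicon rather
    # than an exclusive depression lexicon, so the class signal is carried by
    # emotion words (concentrated negativity) instead of a giveaway token that
    # any full-history model can key on.  This is the regime each module is
    # for: the emotion net supplies the discriminative feature, selection
    # prunes ambiguous content, attention orders what remains.
    lexicons = dict(synthetic_data.DEFAULT_LEXICONS)
    lexicons["depression_indicator"] = list(synthetic_data.NEGATIVE_WORDS)
    f1s: dict[str, list[float]] = {v: [] for v in variants}
    for k in range(n_seeds):
        run_seed = seed + 10 * k
        gen = GeneratorConfig(n_users=n_users, posts_per_user=(20, 20),
                              indicator_fraction=0.15, noise_rate=0.05,
                              seed=run_seed, lexicons=lexicons)
        wb = make_workbench(gen, run_seed)
        reports = trainer_eval.run_ablation(
            wb.histories, wb.vocab, wb.config, wb.emotion_params, run_seed,
            variants=variants)
        for v in variants:
            f1s[v].append(reports[v].f1)
    medians = {v: float(np.median(f1s[v])) for v in variants}
    return medians | {"per_seed": f1s}


# --------------------------------------------------------------------------
# REINFORCE estimator vs exhaustive enumeration
# --------------------------------------------------------------------------

class TableReward:
    """Reward model for toy problems: a fixed table over selection subsets."""

    def __init__(self, table: dict[tuple[int, ...], float]):
        self.table = table

    def reward_for_masks(self, masks: np.ndarray) -> np.ndarray:
        return np.asarray([self.table[tuple(int(a) for a in row)] for row in masks])


def toy_problem(seed: int, T: int = 3, post_dim: int = 2, emo_dim: int = 1,
                hidden: int = 4):
    """A T-post toy with a random reward table; small enough for exhaustive
    enumeration of all 2^T episodes."""
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(T, post_dim))
    E = rng.normal(size=(T, emo_dim))
    policy = PolicyParams(2 * post_dim + emo_dim, rng, hidden_dim=hidden)
    table = {a: float(r) for a, r in zip(
        itertools.product((0, 1), repeat=T),
        rng.uniform(0.05, 0.95, size=2 ** T))}
    return P, E, policy, TableReward(table)


def enumerate_episodes(P: np.ndarray, E: np.ndarray | None,
                       policy: PolicyParams, reward: TableReward,
                       ) -> list[tuple[np.ndarray, float, float]]:
    """All 2^T episodes as (actions, probability, reward) triples.

    States are rebuilt per action prefix exactly as the sampler builds them,
    so the enumeration covers the true episode distribution.
    """
    T = P.shape[0]
    out = []
    for actions in itertools.product((0, 1), repeat=T):
        prob = 1.0
        selected: list[np.ndarray] = []
        for t, a in enumerate(actions):
            from .rl_selector import build_state, policy_prob
            e_t = None if E is None else E[t]
            p1 = policy_prob(build_state(P[t], selected, e_t), policy)
            prob *= p1 if a == 1 else (1.0 - p1)
            if a == 1:
                selected.append(P[t])
        r = reward.reward_for_masks(np.asarray(actions)[None, :])[0]
        out.append((np.asarray(actions), prob, float(r)))
    return out


def exact_expected_reward(P, E, policy, reward) -> float:
    return sum(prob * r for _, prob, r in enumerate_episodes(P, E, policy, reward))


def finite_difference_gradient(P, E, policy, reward, eps: float = 1e-5) -> list[np.ndarray]:
    """Central finite differences of the exact expected reward with respect
    to every policy parameter: the independent oracle."""
    grads = []
    for p in policy.parameters():
        g = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = p.data[i]
            p.data[i] = orig + eps
            jp = exact_expected_reward(P, E, policy, reward)
            p.data[i] = orig - eps
            jm = exact_expected_reward(P, E, policy, reward)
            p.data[i] = orig
            g[i] = (jp - jm) / (2 * eps)
        grads.append(g)
    return grads


def sampled_gradient(P, E, policy, reward, n_samples: int,
                     rng: np.random.Generator, use_baseline: bool = True,
                     ) -> list[np.ndarray]:
    """REINFORCE estimate of the expected-reward gradient from n sampled
    episodes."""
    episodes = sample_episodes(P, E, policy, n_samples, rng)
    masks = np.stack([ep.actions for ep in episodes]).astype(np.float64)
    rewards = reward.reward_for_masks(masks)
    for ep, r in zip(episodes, rewards):
        ep.reward = float(r)
    return reinforce_gradient(episodes, policy, use_baseline=use_baseline)


def reinforce_check(seed: int, n_samples: int = 50_000,
                    n_var_batches: int = 300, var_batch: int = 25) -> dict:
    """Compare the sampled REINFORCE gradient with the finite-difference
    gradient of the exact expected reward on the T=3 toy, and measure the
    variance reduction from the mean-reward baseline."""
    P, E, policy, reward = toy_problem(seed)
    rng = np.random.default_rng(seed + 1)
    g_exact = finite_difference_gradient(P, E, policy, reward)
    g_est = sampled_gradient(P, E, policy, reward, n_samples, rng)
    num = math.sqrt(sum(float(np.sum((a - b) ** 2)) for a, b in zip(g_est, g_exact)))
    den = math.sqrt(sum(float(np.sum(b ** 2)) for b in g_exact))
    rel_error = num / den

    # variance of the per-batch estimator with and without the baseline
    flat = {True: [], False: []}
    for k in range(n_var_batches):
        rng_k = np.random.default_rng(seed + 10_000 + k)
        episodes = sample_episodes(P, E, policy, var_batch, rng_k)
        masks = np.stack([ep.actions for ep in episodes]).astype(np.float64)
        rewards = reward.reward_for_masks(masks)
        for ep, r in zip(episodes, rewards):
            ep.reward = float(r)
        for use_baseline in (True, False):
            g = reinforce_gradient(episodes, policy, use_baseline=use_baseline)
            flat[use_baseline].append(np.concatenate([a.ravel() for a in g]))
    var_with = float(np.var(np.stack(flat[True]), axis=0).sum())
    var_without = float(np.var(np.stack(flat[False]), axis=0).sum())
    return {
        "rel_error": rel_error,
        "var_with_baseline": var_with,
        "var_without_baseline": var_without,
    }
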