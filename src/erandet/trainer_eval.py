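"""End-to-end training, evaluation, ablations and the subset experiment.

Training schedule
-----------------
1. *Warm-up*: the BiLSTM encoder, attention layer and classifier are trained
   on **all** posts (no selection) so the terminal reward is informative
   before the policy ever acts.
2. *Alternating epochs*: per epoch, (a) a REINFORCE pass updates the
   selection policy with the classifier frozen — N episodes are sampled per
   user, the terminal reward is the classifier's probability of the gold
   label given the selected posts, and the within-user mean reward is the
   baseline; then (b) the encoder/attention/classifier are updated on the
   greedily selected posts with the policy frozen.

The emotion TextCNN is pretrained separately and frozen throughout.
Everything is deterministic given (config, seed) on one thread.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .attention_classifier import (
    AttentionParams,
    ClassifierParams,
    attention_pool,
    attention_weights,
    classification_loss,
    classify_user,
    uniform_weights,
)
from .corpus_io import UserHistory, Vocabulary, tokenize_and_pad
from .emotion_net import EmotionNetConfig, TextCnnParams, emotion_vectors, user_emotion_expectation
from .nn import Tensor
from .post_encoder import BiLstmParams, bilstm_encode
from .rl_selector import (
    EMPTY_SELECTION_PENALTY,
    PolicyParams,
    episode_logprob_loss,
    sample_episodes,
    select_posts_greedy,
)


# --------------------------------------------------------------------------
# configuration and metrics
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the reference configuration
    (300-d embeddings, 200 BiLSTM units, dropout 0.5, batch 128, Adam 1e-3)."""

    embedding_dim: int = 300
    bilstm_hidden: int = 200
    dropout: float = 0.5
    batch_size: int = 128
    learning_rate: float = 1e-3
    post_len: int = 32
    policy_hidden: int = 128
    attn_proj_dim: int | None = None     # defaults to bilstm_hidden
    attn_scoring: str = "tanh"           # or "bilinear"
    n_episodes: int = 8                  # N sampled episodes per user per update
    entropy_weight: float = 0.0          # optional policy entropy bonus
    warmup_epochs: int = 2
    epochs: int = 6                      # alternating RL/classifier epochs
    greedy_threshold: float = 0.5
    # ablation switches
    no_rl: bool = False                  # EBAtt: use all posts, no selection
    no_emotion: bool = False             # RLAtt: drop the emotion network entirely
    no_attention: bool = False           # ERN: uniform averaging instead of attention
    no_emotion_in_state: bool = False    # drop e_t from the policy state only

    def validate(self) -> None:
        for name in ("embedding_dim", "bilstm_hidden", "batch_size", "post_len",
                     "policy_hidden", "n_episodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.no_emotion and self.no_emotion_in_state:
            raise ValueError("no_emotion already removes e_t from the state")


def benchmark_config() -> tuple[TrainConfig, EmotionNetConfig]:
    """The compact configuration used for the package's own synthetic-data
    benchmarks (widths scaled down from the reference defaults so full
    training runs complete in seconds on one CPU)."""
    cfg = TrainConfig(
        embedding_dim=32, bilstm_hidden=24, batch_size=16, post_len=12,
        policy_hidden=64, warmup_epochs=10, epochs=18,
    )
    emo = EmotionNetConfig(
        filter_heights=(2, 3), n_filters=16, hidden_dim=16, post_len=12,
        max_epochs=40, batch_size=32, patience=4,
    )
    return cfg, emo


def f1_score(precision: float, recall: float) -> float:
    """F1 = 2PR / (P + R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Accuracy and positive-class (depressed) precision / recall / F1."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            warnings.warn("no predicted positives; precision reported as 0")
            return 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)

    @staticmethod
    def from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return EvalReport(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


# --------------------------------------------------------------------------
# dataset plumbing
# --------------------------------------------------------------------------

@dataclass
class EncodedUser:
    """A user ready for the model: padded token ids plus frozen emotion
    features."""

    user_id: str
    label: int
    ids: np.ndarray                     # (T, n) int64
    texts: list[str]
    emo: np.ndarray | None = None       # (T, d_e) frozen emotion vectors
    v_emo: np.ndarray | None = None     # (d_e,) user emotion expectation

    @property
    def T(self) -> int:
        return self.ids.shape[0]


def prepare_users(histories: Sequence[UserHistory], vocab: Vocabulary, post_len: int,
                  emotion_params: TextCnnParams | None) -> list[EncodedUser]:
    """Tokenize/pad every post and attach frozen emotion features (when an
    emotion net is supplied)."""
    users = []
    for h in histories:
        ids = np.stack([tokenize_and_pad(p.text, vocab, post_len) for p in h.posts])
        user = EncodedUser(user_id=h.user_id, label=h.label, ids=ids,
                           texts=[p.text for p in h.posts])
        if emotion_params is not None:
            emo_len = emotion_params.config.post_len
            emo_ids = np.stack([tokenize_and_pad(p.text, vocab, emo_len) for p in h.posts])
            user.emo = emotion_vectors(emo_ids, emotion_params)
            user.v_emo = user_emotion_expectation(user.emo)
        users.append(user)
    return users


def split_dataset(users: Sequence[EncodedUser], seed: int,
                  test_fraction: float = 0.2, dev_fraction: float = 0.1,
                  ) -> tuple[list[EncodedUser], list[EncodedUser], list[EncodedUser]]:
    """Stratified train/dev/test split (dev carved out of the train part)."""
    rng = np.random.default_rng(seed)
    train, dev, test = [], [], []
    for label in (0, 1):
        group = [u for u in users if u.label == label]
        order = rng.permutation(len(group))
        n_test = int(round(len(group) * test_fraction))
        test.extend(group[i] for i in order[:n_test])
        rest = [group[i] for i in order[n_test:]]
        n_dev = max(1, int(round(len(rest) * dev_fraction)))
        dev.extend(rest[:n_dev])
        train.extend(rest[n_dev:])
    return train, dev, test


def _pad_user_batch(users: Sequence[EncodedUser], post_len: int, d_e: int | None):
    """Stack users into (B, Tmax, n) ids with a (B, Tmax) post mask."""
    B = len(users)
    Tmax = max(u.T for u in users)
    ids = np.zeros((B, Tmax, post_len), dtype=np.int64)
    mask = np.zeros((B, Tmax))
    labels = np.asarray([u.label for u in users], dtype=np.int64)
    v_emo = None
    if d_e is not None:
        v_emo = np.stack([u.v_emo for u in users])
    for i, u in enumerate(users):
        ids[i, :u.T] = u.ids
        mask[i, :u.T] = 1.0
    return ids, mask, labels, v_emo


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class EranModel:
    """Emotion-based reinforcement attention network.

    Holds the trainable embedding table, BiLSTM encoder, attention head,
    2-class classifier and the selection policy, plus the frozen emotion
    TextCNN (absent in the no-emotion ablation).
    """

    def __init__(self, vocab: Vocabulary, config: TrainConfig, seed: int,
                 emotion_params: TextCnnParams | None):
        config.validate()
        if emotion_params is None and not config.no_emotion:
            raise ValueError("emotion_params required unless no_emotion is set")
        self.config = config
        self.vocab = vocab
        self.emotion_params = None if config.no_emotion else emotion_params
        rng = np.random.default_rng(seed)
        self.embedding = Tensor(vocab.embeddings.copy(), requires_grad=True)
        self.bilstm = BiLstmParams(vocab.dim, config.bilstm_hidden, rng)
        post_dim = self.bilstm.output_dim
        proj = config.attn_proj_dim or config.bilstm_hidden
        self.attention = AttentionParams(post_dim, proj, rng, scoring=config.attn_scoring)
        self.d_e = None if self.emotion_params is None else self.emotion_params.config.hidden_dim
        fused = post_dim + (self.d_e or 0)
        self.classifier = ClassifierParams(fused, rng)
        state_dim = 2 * post_dim
        if self.d_e is not None and not config.no_emotion_in_state:
            state_dim += self.d_e
        self.policy = PolicyParams(state_dim, rng, hidden_dim=config.policy_hidden)

    # -- parameter groups -------------------------------------------------
    def classifier_side_parameters(self) -> list[Tensor]:
        return ([self.embedding] + self.bilstm.parameters()
                + self.attention.parameters() + self.classifier.parameters())

    def policy_parameters(self) -> list[Tensor]:
        return self.policy.parameters()

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {"embedding": self.embedding.data}
        groups = {
            "bilstm": self.bilstm.parameters(),
            "attn": self.attention.parameters(),
            "clf": self.classifier.parameters(),
            "policy": self.policy.parameters(),
        }
        for gname, params in groups.items():
            for i, p in enumerate(params):
                arrays[f"{gname}_{i}"] = p.data
        return arrays

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, arr in self.state_arrays().items():
            arr[...] = state[name]

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    # -- forward pieces ----------------------------------------------------
    def encode_posts(self, ids: np.ndarray) -> Tensor:
        """(B, T, n) token ids -> (B, T, 2u) post vectors."""
        B, T, n = ids.shape
        flat = bilstm_encode(ids.reshape(B * T, n), self.embedding, self.bilstm)
        return flat.reshape(B, T, self.bilstm.output_dim)

    def _policy_features(self, user: EncodedUser):
        emo = None
        if self.d_e is not None and not self.config.no_emotion_in_state:
            emo = user.emo
        return emo

    def pooled_from_masks(self, post_vectors: Tensor, masks: np.ndarray) -> Tensor:
        """Attention-pool (or uniform-average for the no-attention ablation)
        over the masked-in posts; rows with an empty mask pool to zero."""
        masks = np.asarray(masks, dtype=np.float64)
        nonempty = masks.sum(axis=-1) > 0
        safe = masks.copy()
        safe[~nonempty] = 1.0
        if self.config.no_attention:
            w = uniform_weights(safe)
        else:
            w = attention_weights(post_vectors, safe, self.attention)
        pooled = attention_pool(post_vectors, w)
        return pooled * Tensor(nonempty[..., None].astype(np.float64))

    def class_probs(self, post_vectors: Tensor, masks: np.ndarray,
                    v_emo: np.ndarray | None) -> Tensor:
        pooled = self.pooled_from_masks(post_vectors, masks)
        v = None if v_emo is None else Tensor(np.asarray(v_emo, dtype=np.float64))
        return classify_user(pooled, v, self.classifier)

    # -- inference ----------------------------------------------------------
    def greedy_selection(self, user: EncodedUser,
                         post_vectors: np.ndarray | None = None) -> tuple[list[int], list[int]]:
        if self.config.no_rl:
            return list(range(user.T)), []
        if post_vectors is None:
            post_vectors = self.encode_posts(user.ids[None]).data[0]
        return select_posts_greedy(post_vectors, self._policy_features(user),
                                   self.policy, self.config.greedy_threshold)

    def predict(self, users: Sequence[EncodedUser]) -> tuple[np.ndarray, dict[str, set[int]]]:
        """Greedy-select then classify each user; returns (predictions,
        selected indices per user)."""
        preds = np.empty(len(users), dtype=np.int64)
        selections: dict[str, set[int]] = {}
        for i, user in enumerate(users):
            P = self.encode_posts(user.ids[None]).data[0]
            dep, _ = self.greedy_selection(user, P)
            selections[user.user_id] = set(dep)
            mask = np.zeros((1, user.T))
            mask[0, dep] = 1.0
            v_emo = None if self.d_e is None else user.v_emo[None]
            probs = self.class_probs(Tensor(P[None]), mask, v_emo)
            preds[i] = int(np.argmax(probs.data[0]))
        return preds, selections


class UserRewardModel:
    """Terminal reward for one user's episodes: the classifier's probability
    of the gold label given each selection mask (no gradients)."""

    def __init__(self, model: EranModel, post_vectors: np.ndarray,
                 v_emo: np.ndarray | None, gold: int):
        self.model = model
        self.post_vectors = np.asarray(post_vectors, dtype=np.float64)
        self.v_emo = v_emo
        self.gold = int(gold)

    def reward_for_masks(self, masks: np.ndarray) -> np.ndarray:
        masks = np.asarray(masks, dtype=np.float64)
        N = masks.shape[0]
        P = Tensor(np.broadcast_to(self.post_vectors, (N, *self.post_vectors.shape)))
        v_emo = None if self.v_emo is None else np.broadcast_to(
            self.v_emo, (N, self.v_emo.shape[0]))
        probs = self.model.class_probs(P, masks, v_emo)
        r = probs.data[:, self.gold].copy()
        r[masks.sum(axis=1) == 0] -= EMPTY_SELECTION_PENALTY
        return r


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _dropout_mask(shape, rate: float, rng: np.random.Generator) -> Tensor:
    keep = (rng.random(shape) >= rate).astype(np.float64) / (1.0 - rate)
    return Tensor(keep)


def _classifier_batch_step(model: EranModel, users: Sequence[EncodedUser],
                           masks_fn, opt: nn.Adam, rng: np.random.Generator) -> float:
    """One gradient step on the classifier side for a batch of users.
    `masks_fn(users, post_vectors_data, user_mask)` returns selection masks."""
    cfg = model.config
    ids, user_mask, labels, v_emo = _pad_user_batch(users, cfg.post_len, model.d_e)
    P = model.encode_posts(ids)
    sel = masks_fn(users, P.data, user_mask)
    sel = sel * user_mask
    if cfg.dropout > 0:
        P = P * _dropout_mask(P.shape, cfg.dropout, rng)
    probs = model.class_probs(P, sel, v_emo)
    loss = classification_loss(probs, labels)
    opt.zero_grad()
    loss.backward()
    opt.step()
    return loss.item()


def _greedy_masks(model: EranModel):
    def fn(users, P_data, user_mask):
        masks = np.zeros_like(user_mask)
        for i, u in enumerate(users):
            dep, _ = model.greedy_selection(u, P_data[i, :u.T])
            masks[i, dep] = 1.0
        return masks
    return fn


def _all_masks(users, P_data, user_mask):
    return user_mask.copy()


def train(train_users: Sequence[EncodedUser], dev_users: Sequence[EncodedUser],
          vocab: Vocabulary, config: TrainConfig, seed: int,
          emotion_params: TextCnnParams | None,
          log: list[dict] | None = None) -> EranModel:
    """Full training schedule; checkpoints on best dev F1.

    Raises if the training set is single-class (the reward and the loss are
    meaningless without both labels).
    """
    labels = {u.label for u in train_users}
    if labels != {0, 1}:
        raise ValueError("training set must contain both classes")
    config.validate()
    model = EranModel(vocab, config, seed, emotion_params)
    rng = np.random.default_rng(seed + 101)
    clf_opt = nn.Adam(model.classifier_side_parameters(), lr=config.learning_rate)
    pol_opt = nn.Adam(model.policy_parameters(), lr=config.learning_rate)
    # checkpoint comparisons below use >=: when dev F1 ties (it saturates
    # quickly on separable data), keep the *latest* state so continued policy
    # refinement (rising mean reward at constant dev F1) is not discarded
    best = (-1.0, model.snapshot())

    def log_epoch(**kw):
        if log is not None:
            log.append(kw)

    def dev_f1() -> float:
        preds, _ = model.predict(dev_users)
        return EvalReport.from_predictions([u.label for u in dev_users], preds).f1

    users = list(train_users)
    # --- phase 1: warm-up on all posts -----------------------------------
    for epoch in range(config.warmup_epochs):
        order = rng.permutation(len(users))
        total, nb = 0.0, 0
        for start in range(0, len(users), config.batch_size):
            batch = [users[i] for i in order[start:start + config.batch_size]]
            total += _classifier_batch_step(model, batch, _all_masks, clf_opt, rng)
            nb += 1
        f1 = dev_f1()
        log_epoch(phase="warmup", epoch=epoch, loss_2=total / max(nb, 1), dev_f1=f1)
        if f1 >= best[0]:
            best = (f1, model.snapshot())

    if config.no_rl:
        # EBAtt: no selection layer; warm-up training *is* the training
        extra = config.epochs
        for epoch in range(extra):
            order = rng.permutation(len(users))
            total, nb = 0.0, 0
            for start in range(0, len(users), config.batch_size):
                batch = [users[i] for i in order[start:start + config.batch_size]]
                total += _classifier_batch_step(model, batch, _all_masks, clf_opt, rng)
                nb += 1
            f1 = dev_f1()
            log_epoch(phase="all-posts", epoch=epoch, loss_2=total / max(nb, 1), dev_f1=f1)
            if f1 >= best[0]:
                best = (f1, model.snapshot())
        model.load_state(best[1])
        return model

    # --- phase 2: alternate policy / classifier updates -------------------
    for epoch in range(config.epochs):
        # (a) policy pass, classifier frozen
        order = rng.permutation(len(users))
        loss1_total, reward_total, sel_total, n_ep = 0.0, 0.0, 0.0, 0
        for i in order:
            user = users[i]
            P = model.encode_posts(user.ids[None]).data[0]
            episodes = sample_episodes(P, model._policy_features(user),
                                       model.policy, config.n_episodes, rng)
            rm = UserRewardModel(model, P, user.v_emo if model.d_e else None, user.label)
            masks = np.stack([ep.actions for ep in episodes]).astype(np.float64)
            rewards = rm.reward_for_masks(masks)
            for ep, r in zip(episodes, rewards):
                ep.reward = float(r)
            loss1, _ = episode_logprob_loss(episodes, model.policy,
                                            entropy_weight=config.entropy_weight)
            pol_opt.zero_grad()
            loss1.backward()
            pol_opt.step()
            loss1_total += loss1.item()
            reward_total += rewards.mean()
            sel_total += masks.mean()
            n_ep += 1
        # (b) classifier pass on greedy selections, policy frozen
        order = rng.permutation(len(users))
        total, nb = 0.0, 0
        for start in range(0, len(users), config.batch_size):
            batch = [users[i] for i in order[start:start + config.batch_size]]
            total += _classifier_batch_step(model, batch, _greedy_masks(model), clf_opt, rng)
            nb += 1
        f1 = dev_f1()
        log_epoch(phase="alternate", epoch=epoch, loss_1=loss1_total / n_ep,
                  mean_reward=reward_total / n_ep, selection_rate=sel_total / n_ep,
                  loss_2=total / max(nb, 1), dev_f1=f1)
        if f1 >= best[0]:
            best = (f1, model.snapshot())
    model.load_state(best[1])
    return model


def evaluate(model: EranModel, users: Sequence[EncodedUser]) -> EvalReport:
    """Greedy-select, classify, and score on the depressed class."""
    preds, _ = model.predict(users)
    return EvalReport.from_predictions([u.label for u in users], preds)


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------

ABLATION_VARIANTS = ("ERAN", "EBAtt", "RLAtt", "ERN", "no_emotion_in_state")


def _variant_config(base: TrainConfig, variant: str) -> TrainConfig:
    cfg = TrainConfig(**asdict(base))
    if variant == "ERAN":
        pass
    elif variant == "EBAtt":
        cfg.no_rl = True
    elif variant == "RLAtt":
        cfg.no_emotion = True
    elif variant == "ERN":
        cfg.no_attention = True
    elif variant == "no_emotion_in_state":
        cfg.no_emotion_in_state = True
    else:
        raise ValueError(f"unknown ablation variant {variant!r}")
    return cfg


def run_ablation(histories, vocab: Vocabulary, base_config: TrainConfig,
                 emotion_params: TextCnnParams, seed: int,
                 variants: Sequence[str] = ABLATION_VARIANTS) -> dict[str, EvalReport]:
    """Train every ablation variant with a shared split/seed/schedule and
    return test-set reports."""
    reports: dict[str, EvalReport] = {}
    for variant in variants:
        cfg = _variant_config(base_config, variant)
        emo = None if cfg.no_emotion else emotion_params
        users = prepare_users(histories, vocab, cfg.post_len, emo)
        tr, dev, te = split_dataset(users, seed)
        model = train(tr, dev, vocab, cfg, seed, emo)
        reports[variant] = evaluate(model, te)
    return reports


# -- independent BiLSTM baseline for the subset experiment ------------------

class _BilstmBaseline:
    """BiLSTM post encoder + mean pooling over posts + 2-class softmax;
    the independent probe model trained on each materialized subset."""

    def __init__(self, vocab: Vocabulary, hidden: int, seed: int):
        rng = np.random.default_rng(seed)
        self.embedding = Tensor(vocab.embeddings.copy(), requires_grad=True)
        self.bilstm = BiLstmParams(vocab.dim, hidden, rng)
        self.head = nn.Linear(self.bilstm.output_dim, 2, rng)

    def parameters(self):
        return [self.embedding] + self.bilstm.parameters() + self.head.parameters()

    def probs(self, ids: np.ndarray, user_mask: np.ndarray) -> Tensor:
        B, T, n = ids.shape
        flat = bilstm_encode(ids.reshape(B * T, n), self.embedding, self.bilstm)
        P = flat.reshape(B, T, self.bilstm.output_dim)
        denom = np.maximum(user_mask.sum(axis=1, keepdims=True), 1.0)
        pooled = (P * Tensor(user_mask[..., None])).sum(axis=1) * Tensor(1.0 / denom)
        from .attention_classifier import softmax2
        return softmax2(self.head(pooled))


def train_bilstm_baseline(train_users: Sequence[EncodedUser],
                          test_users: Sequence[EncodedUser],
                          vocab: Vocabulary, seed: int, hidden: int = 16,
                          epochs: int = 12, batch_size: int = 16,
                          lr: float = 3e-3, post_len: int = 12) -> EvalReport:
    model = _BilstmBaseline(vocab, hidden, seed)
    rng = np.random.default_rng(seed + 7)
    opt = nn.Adam(model.parameters(), lr=lr)
    users = list(train_users)
    for _ in range(epochs):
        order = rng.permutation(len(users))
        for start in range(0, len(users), batch_size):
            batch = [users[i] for i in order[start:start + batch_size]]
            ids, mask, labels, _ = _pad_user_batch(batch, post_len, None)
            probs = model.probs(ids, mask)
            loss = classification_loss(probs, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
    ids, mask, labels, _ = _pad_user_batch(list(test_users), post_len, None)
    preds = np.argmax(model.probs(ids, mask).data, axis=1)
    return EvalReport.from_predictions(labels, preds)


def _subset_user(user: EncodedUser, indices: Sequence[int]) -> EncodedUser | None:
    if not indices:
        return None
    idx = sorted(indices)
    return EncodedUser(
        user_id=user.user_id, label=user.label, ids=user.ids[idx],
        texts=[user.texts[i] for i in idx],
        emo=None if user.emo is None else user.emo[idx],
        v_emo=None if user.emo is None else user.emo[idx].mean(axis=0),
    )


def materialize_subsets(model: EranModel, users: Sequence[EncodedUser],
                        sample_rng: np.random.Generator | None = None,
                        ) -> dict[str, list[EncodedUser]]:
    """Partition every user's posts with the selector into the selected
    (H^dep), unselected (H^non) and original (H^orig) datasets.
    Users whose subset is empty are dropped from that subset.

    With ``sample_rng`` the partition is *sampled* from the policy instead of
    greedily thresholded — the right null control for an untrained policy,
    whose greedy determinization would otherwise split posts along an
    arbitrary fixed hyperplane rather than at random."""
    out: dict[str, list[EncodedUser]] = {"dep": [], "non": [], "orig": []}
    for user in users:
        if sample_rng is not None:
            P = model.encode_posts(user.ids[None]).data[0]
            ep = sample_episodes(P, model._policy_features(user), model.policy,
                                 1, sample_rng)[0]
            dep, non = ep.dep_indices, ep.non_indices
        else:
            dep, non = model.greedy_selection(user)
        out["orig"].append(user)
        u_dep = _subset_user(user, dep)
        u_non = _subset_user(user, non)
        if u_dep is not None:
            out["dep"].append(u_dep)
        if u_non is not None:
            out["non"].append(u_non)
    return out


def subset_experiment(model: EranModel, train_users: Sequence[EncodedUser],
                      test_users: Sequence[EncodedUser], vocab: Vocabulary,
                      seed: int, baseline_epochs: int = 12,
                      post_len: int | None = None,
                      sample_selection: bool = False) -> dict[str, EvalReport]:
    """Train the independent BiLSTM baseline on H^dep / H^non / H^orig and
    report test metrics for each (the selected-subset effectiveness probe)."""
    post_len = post_len or model.config.post_len
    rng = np.random.default_rng(seed + 31) if sample_selection else None
    tr = materialize_subsets(model, train_users, sample_rng=rng)
    te = materialize_subsets(model, test_users, sample_rng=rng)
    reports = {}
    for name in ("dep", "non", "orig"):
        reports[name] = train_bilstm_baseline(
            tr[name], te[name], vocab, seed, epochs=baseline_epochs, post_len=post_len)
    return reports


def export_attention_viz(model: EranModel, users: Sequence[EncodedUser],
                         tsv_path: str | Path, html_path: str | Path | None = None,
                         ) -> dict[str, list[tuple[int, float, str]]]:
    """Dump per-user attention weights over the selected posts as TSV
    (user_id, post index, weight, text), optionally with an HTML heat-map."""
    rows: dict[str, list[tuple[int, float, str]]] = {}
    for user in users:
        P = model.encode_posts(user.ids[None]).data[0]
        dep, _ = model.greedy_selection(user, P)
        if not dep:
            rows[user.user_id] = []
            continue
        mask = np.zeros((1, user.T))
        mask[0, dep] = 1.0
        if model.config.no_attention:
            w = uniform_weights(mask).data[0]
        else:
            w = attention_weights(Tensor(P[None]), mask, model.attention).data[0]
        rows[user.user_id] = [(t, float(w[t]), user.texts[t]) for t in dep]
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("user_id\tpost_index\tattention_weight\ttext\n")
        for uid, items in rows.items():
            for t, weight, text in items:
                fh.write(f"{uid}\t{t}\t{weight:.6f}\t{text}\n")
    if html_path is not None:
        _write_viz_html(rows, html_path)
    return rows


def _write_viz_html(rows, path) -> None:
    parts = ["<html><body>"]
    for uid, items in rows.items():
        parts.append(f"<h3>{uid}</h3>")
        for t, weight, text in items:
            shade = int(255 * (1.0 - min(weight, 1.0)))
            parts.append(
                f'<div style="background: rgb(255,{shade},{shade})">'
                f"[{t}] w={weight:.3f} {text}</div>"
            )
    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")


def write_log(log: list[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
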