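"""Policy-gradient selection of depression-indicator posts.

The agent walks a user's posts in chronological order.  At step t its state
is the concatenation of

* the current post's BiLSTM vector p_t,
* the average of the post vectors already selected (zero vector while the
  selected set is empty), and
* the current post's emotion vector e_t (omitted in the state-ablation
  variant),

and it selects (a_t = 1) or skips (a_t = 0) the post with probability given
by a small MLP with a sigmoid head.  After the last post the classifier
returns a terminal reward R(tau) = p(gold label | selected set), and the
policy is updated with REINFORCE using the (leave-one-out) mean reward of
the N sampled episodes as the baseline b: maximizing the expected reward is
minimizing

    loss_1(theta) = -(1/N) sum_n (R(tau_n) - b) sum_t log p_theta(a_t | s_t).

An episode that selects nothing is scored on a zero pooled vector and
penalized by -0.5 so the all-skip policy is never attractive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from . import nn
from .nn import Tensor

EMPTY_SELECTION_PENALTY = 0.5


class PolicyParams:
    """Selection policy: MLP(state) -> P(select) in (0,1)."""

    def __init__(self, state_dim: int, rng: np.random.Generator, hidden_dim: int = 128):
        self.state_dim = state_dim
        self.hidden = nn.Linear(state_dim, hidden_dim, rng)
        self.out = nn.Linear(hidden_dim, 1, rng)
        # zero head: the initial policy is exactly uniform (P(select) = 0.5
        # for every state), giving unbiased maximum-entropy exploration
        self.out.W.data[:] = 0.0

    def parameters(self) -> list[Tensor]:
        return self.hidden.parameters() + self.out.parameters()

    def logits(self, states: Tensor) -> Tensor:
        """Pre-sigmoid selection logits for a batch of states (..., state_dim)."""
        return self.out(self.hidden(states).tanh())[..., 0]

    def prob(self, states: np.ndarray) -> np.ndarray:
        """P(a=1 | s) without gradient tracking."""
        z = self.logits(Tensor(np.asarray(states, dtype=np.float64))).data
        return 1.0 / (1.0 + np.exp(-z))


def build_state(p_t: np.ndarray, selected: Sequence[np.ndarray] | np.ndarray,
                e_t: np.ndarray | None) -> np.ndarray:
    """Policy state [p_t ; avg(selected) ; e_t]; zero average when nothing is
    selected yet; e_t=None drops the emotion block (state ablation)."""
    p_t = np.asarray(p_t, dtype=np.float64)
    selected = list(selected)
    if selected:
        avg = np.mean([np.asarray(v, dtype=np.float64) for v in selected], axis=0)
        if avg.shape != p_t.shape:
            raise ValueError(f"selected-average dim {avg.shape} != post dim {p_t.shape}")
    else:
        avg = np.zeros_like(p_t)
    parts = [p_t, avg]
    if e_t is not None:
        parts.append(np.asarray(e_t, dtype=np.float64))
    return np.concatenate(parts)


def policy_prob(state: np.ndarray, params: PolicyParams) -> float:
    """P(select | state) for a single state vector."""
    return float(params.prob(np.asarray(state)[None, :])[0])


@dataclass
class Episode:
    """One pass of select/skip decisions over a user's T posts."""

    states: np.ndarray        # (T, state_dim)
    actions: np.ndarray       # (T,) in {0,1}
    reward: float = np.nan

    @property
    def dep_indices(self) -> list[int]:
        return [t for t, a in enumerate(self.actions) if a == 1]

    @property
    def non_indices(self) -> list[int]:
        return [t for t, a in enumerate(self.actions) if a == 0]


class RewardModel(Protocol):
    """Terminal reward provider: probability of the gold label given the
    selected subset of one user's posts, as a batch over selection masks."""

    def reward_for_masks(self, masks: np.ndarray) -> np.ndarray:
        ...


def _states_step(post_vectors: np.ndarray, emotion_vectors: np.ndarray | None,
                 sel_sum: np.ndarray, sel_cnt: np.ndarray, t: int) -> np.ndarray:
    """States for N parallel episodes at step t.

    sel_sum (N, 2u) and sel_cnt (N,) track each episode's selected set.
    """
    N = sel_sum.shape[0]
    p_t = np.broadcast_to(post_vectors[t], (N, post_vectors.shape[1]))
    avg = np.where(sel_cnt[:, None] > 0, sel_sum / np.maximum(sel_cnt, 1.0)[:, None], 0.0)
    parts = [p_t, avg]
    if emotion_vectors is not None:
        parts.append(np.broadcast_to(emotion_vectors[t], (N, emotion_vectors.shape[1])))
    return np.concatenate(parts, axis=1)


def sample_episodes(post_vectors: np.ndarray, emotion_vectors: np.ndarray | None,
                    params: PolicyParams, n_episodes: int,
                    rng: np.random.Generator) -> list[Episode]:
    """Sample N episodes for one user in parallel (rewards left unset)."""
    post_vectors = np.asarray(post_vectors, dtype=np.float64)
    T, pdim = post_vectors.shape
    N = n_episodes
    sel_sum = np.zeros((N, pdim))
    sel_cnt = np.zeros(N)
    states = np.empty((N, T, params.state_dim))
    actions = np.empty((N, T), dtype=np.int64)
    for t in range(T):
        s_t = _states_step(post_vectors, emotion_vectors, sel_sum, sel_cnt, t)
        p = params.prob(s_t)
        a = (rng.random(N) < p).astype(np.int64)
        states[:, t, :] = s_t
        actions[:, t] = a
        picked = a == 1
        sel_sum[picked] += post_vectors[t]
        sel_cnt[picked] += 1
    return [Episode(states=states[i], actions=actions[i]) for i in range(N)]


def sample_episode(post_vectors: np.ndarray, emotion_vectors: np.ndarray | None,
                   params: PolicyParams, rng: np.random.Generator) -> Episode:
    """Sample a single episode over one user's posts."""
    return sample_episodes(post_vectors, emotion_vectors, params, 1, rng)[0]


def select_posts_greedy(post_vectors: np.ndarray, emotion_vectors: np.ndarray | None,
                        params: PolicyParams,
                        threshold: float = 0.5) -> tuple[list[int], list[int]]:
    """Deterministic inference: select post t iff P(select | s_t) > threshold,
    with states built from the greedily selected set."""
    post_vectors = np.asarray(post_vectors, dtype=np.float64)
    T = post_vectors.shape[0]
    dep: list[int] = []
    non: list[int] = []
    selected: list[np.ndarray] = []
    for t in range(T):
        e_t = None if emotion_vectors is None else emotion_vectors[t]
        s = build_state(post_vectors[t], selected, e_t)
        if policy_prob(s, params) > threshold:
            dep.append(t)
            selected.append(post_vectors[t])
        else:
            non.append(t)
    return dep, non


def compute_reward(episode: Episode, reward_model: RewardModel) -> float:
    """Terminal reward of one episode: the classifier's probability of the
    gold label given the selected posts (empty selection handled by the
    reward model with the -0.5 penalty)."""
    mask = episode.actions[None, :].astype(np.float64)
    r = float(reward_model.reward_for_masks(mask)[0])
    episode.reward = r
    return r


def episode_logprob_loss(episodes: Sequence[Episode], params: PolicyParams,
                         baseline: float | None = None,
                         entropy_weight: float = 0.0) -> tuple[Tensor, float]:
    """REINFORCE surrogate loss over N episodes of one user.

    Returns (loss_1 tensor, mean baseline).  Rewards must already be set.
    By default each episode is baselined against the *leave-one-out* mean of
    the other rewards, which keeps the gradient estimator exactly unbiased
    (the plain within-batch mean would leak each episode's own reward into
    its baseline, an O(1/N) bias); a fixed scalar baseline may be supplied
    instead (0.0 disables baselining).

    With entropy_weight > 0 the mean per-decision Bernoulli entropy is
    subtracted from the loss (an entropy bonus), keeping selection
    probabilities away from the extremes so a post that the policy has
    wrongly learned to skip keeps being sampled occasionally and can be
    corrected by its reward contrast.
    """
    N = len(episodes)
    rewards = np.array([ep.reward for ep in episodes])
    if np.any(np.isnan(rewards)):
        raise ValueError("episodes must have rewards before the policy update")
    if baseline is None:
        if N < 2:
            raise ValueError("leave-one-out baseline needs N >= 2 episodes")
        b = float(rewards.mean())
        adv = (rewards * N - rewards.sum()) / (N - 1)
    else:
        b = float(baseline)
        adv = rewards - b
    states = np.stack([ep.states for ep in episodes])     # (N, T, dim)
    actions = np.stack([ep.actions for ep in episodes]).astype(np.float64)
    logits = params.logits(Tensor(states))                # (N, T)
    p = logits.sigmoid()
    eps = 1e-12
    logp = (Tensor(actions) * (p + eps).log()
            + Tensor(1.0 - actions) * (Tensor(np.ones_like(actions)) - p + eps).log())
    per_episode = logp.sum(axis=1)                        # (N,)
    loss = -(Tensor(adv) * per_episode).sum() * (1.0 / N)
    if entropy_weight > 0.0:
        one = Tensor(np.ones_like(actions))
        entropy = -(p * (p + eps).log() + (one - p) * (one - p + eps).log()).mean()
        loss = loss - entropy * entropy_weight
    return loss, b


def reinforce_update(episodes: Sequence[Episode], params: PolicyParams,
                     learning_rate: float) -> float:
    """Plain-gradient REINFORCE ascent step; returns loss_1.

    The leave-one-out mean reward is the baseline, so if all N rewards are
    equal every advantage is zero and the parameters are unchanged.
    """
    if len(episodes) < 2:
        raise ValueError("need N >= 2 episodes for the mean-reward baseline")
    loss, _ = episode_logprob_loss(episodes, params)
    for p in params.parameters():
        p.grad = None
    loss.backward()
    for p in params.parameters():
        if p.grad is not None:
            p.data -= learning_rate * p.grad
    return loss.item()


def reinforce_gradient(episodes: Sequence[Episode], params: PolicyParams,
                       use_baseline: bool = True) -> list[np.ndarray]:
    """The REINFORCE gradient estimate of the *expected reward* (ascent
    direction) for analysis; does not modify parameters."""
    loss, _ = episode_logprob_loss(
        episodes, params, baseline=None if use_baseline else 0.0
    )
    for p in params.parameters():
        p.grad = None
    loss.backward()
    return [-p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in params.parameters()]
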