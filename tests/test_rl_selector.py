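"""Policy mechanics, episode sampling and the REINFORCE estimator."""

import numpy as np
import pytest

from erandet.experiments import (
    TableReward,
    enumerate_episodes,
    exact_expected_reward,
    finite_difference_gradient,
    sampled_gradient,
    toy_problem,
)
from erandet.rl_selector import (
    Episode,
    PolicyParams,
    build_state,
    compute_reward,
    policy_prob,
    reinforce_update,
    sample_episode,
    sample_episodes,
    select_posts_greedy,
)


def forced_policy(state_dim, logit):
    """A policy whose output is constant regardless of the state."""
    params = PolicyParams(state_dim, np.random.default_rng(0), hidden_dim=4)
    params.hidden.W.data[:] = 0.0
    params.hidden.b.data[:] = 0.0
    params.out.W.data[:] = 0.0
    params.out.b.data[:] = logit
    return params


class TestBuildState:
    def test_empty_selection_gives_zero_average_block(self):
        s = build_state(np.array([1.0, 2.0]), [], np.array([3.0]))
        assert np.array_equal(s, [1.0, 2.0, 0.0, 0.0, 3.0])

    def test_single_selected_vector_is_the_average(self):
        s = build_state(np.array([1.0, 2.0]), [np.array([5.0, 6.0])], None)
        assert np.array_equal(s, [1.0, 2.0, 5.0, 6.0])

    def test_average_matches_naive_mean(self, rng):
        vs = [rng.normal(size=4) for _ in range(5)]
        s = build_state(rng.normal(size=4), vs, None)
        assert np.allclose(s[4:], sum(vs) / 5.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_state(np.ones(3), [np.ones(2)], None)


class TestPolicyProb:
    def test_zero_network_gives_half(self):
        params = forced_policy(4, 0.0)
        assert policy_prob(np.ones(4), params) == pytest.approx(0.5)

    def test_action_probabilities_sum_to_one(self, rng):
        params = PolicyParams(4, rng)
        p1 = policy_prob(rng.normal(size=4), params)
        assert 0.0 < p1 < 1.0  # complement is 1 - p1 by construction

    def test_logit_shift_increases_selection_probability(self, rng):
        params = PolicyParams(4, rng)
        s = rng.normal(size=4)
        p_before = policy_prob(s, params)
        params.out.b.data[0] += 1.5
        assert policy_prob(s, params) > p_before


class TestEpisodes:
    def test_forced_select_all_and_none(self, rng):
        P = rng.normal(size=(6, 2))
        for logit, expected_dep in ((20.0, list(range(6))), (-20.0, [])):
            params = forced_policy(4, logit)
            ep = sample_episode(P, None, params, np.random.default_rng(0))
            assert ep.dep_indices == expected_dep
            assert sorted(ep.dep_indices + ep.non_indices) == list(range(6))

    def test_partition_invariant_over_random_policies(self, rng):
        P = rng.normal(size=(8, 3))
        E = rng.normal(size=(8, 2))
        params = PolicyParams(8, rng, hidden_dim=6)
        for ep in sample_episodes(P, E, params, 20, rng):
            dep, non = set(ep.dep_indices), set(ep.non_indices)
            assert dep | non == set(range(8)) and not dep & non

    def test_empirical_selection_frequency_matches_policy(self, rng):
        """First-step selection frequency over 10,000 episodes is binomial
        around the policy probability (within 3 standard errors)."""
        P = rng.normal(size=(3, 2))
        E = rng.normal(size=(3, 1))
        params = PolicyParams(5, rng, hidden_dim=4)
        params.out.b.data[0] = 0.7  # move away from 0.5
        p = policy_prob(build_state(P[0], [], E[0]), params)
        eps = sample_episodes(P, E, params, 10_000, np.random.default_rng(1))
        freq = np.mean([ep.actions[0] for ep in eps])
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(freq - p) <= 3 * se

    def test_greedy_selection_partitions_and_respects_forcing(self, rng):
        P = rng.normal(size=(5, 2))
        dep, non = select_posts_greedy(P, None, forced_policy(4, 10.0))
        assert dep == list(range(5)) and non == []
        dep, non = select_posts_greedy(P, None, forced_policy(4, -10.0))
        assert dep == [] and sorted(non) == list(range(5))

    def test_reward_is_pure(self):
        table = TableReward({(0, 1): 0.7, (1, 1): 0.9, (0, 0): 0.1, (1, 0): 0.4})
        ep = Episode(states=np.zeros((2, 4)), actions=np.array([0, 1]))
        r1 = compute_reward(ep, table)
        r2 = compute_reward(ep, table)
        assert r1 == r2 == 0.7


class TestReinforce:
    def test_equal_rewards_leave_parameters_unchanged(self, rng):
        """With the mean baseline, identical rewards give zero advantage."""
        params = PolicyParams(5, rng, hidden_dim=4)
        before = [p.data.copy() for p in params.parameters()]
        P, E = rng.normal(size=(3, 2)), rng.normal(size=(3, 1))
        episodes = sample_episodes(P, E, params, 4, rng)
        for ep in episodes:
            ep.reward = 0.6
        reinforce_update(episodes, params, learning_rate=0.5)
        for b, p in zip(before, params.parameters()):
            assert np.array_equal(b, p.data)

    def test_single_episode_rejected(self, rng):
        params = PolicyParams(5, rng, hidden_dim=4)
        ep = sample_episode(rng.normal(size=(3, 2)), rng.normal(size=(3, 1)), params, rng)
        ep.reward = 0.5
        with pytest.raises(ValueError):
            reinforce_update([ep], params, 0.1)

    def test_two_post_toy_learns_optimal_selection(self, rng):
        """Selecting post 1 yields reward 0.9, skipping it 0.1; REINFORCE
        should drive the selection probability above 0.9."""
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        table = TableReward({(1, 0): 0.9, (1, 1): 0.9, (0, 0): 0.1, (0, 1): 0.1})
        params = PolicyParams(4, np.random.default_rng(0), hidden_dim=4)
        sample_rng = np.random.default_rng(1)
        for _ in range(500):
            episodes = sample_episodes(P, None, params, 8, sample_rng)
            masks = np.stack([ep.actions for ep in episodes]).astype(float)
            for ep, r in zip(episodes, table.reward_for_masks(masks)):
                ep.reward = float(r)
            reinforce_update(episodes, params, learning_rate=0.05)
        assert policy_prob(build_state(P[0], [], None), params) > 0.9

    def test_gradient_matches_exhaustive_enumeration(self):
        """Sampled REINFORCE gradient vs finite differences of the exact
        expected reward (all 8 episodes of a T=3 toy enumerated)."""
        P, E, policy, reward = toy_problem(seed=3)
        g_exact = finite_difference_gradient(P, E, policy, reward)
        g_est = sampled_gradient(P, E, policy, reward, 50_000,
                                 np.random.default_rng(0))
        num = np.sqrt(sum(np.sum((a - b) ** 2) for a, b in zip(g_est, g_exact)))
        den = np.sqrt(sum(np.sum(b ** 2) for b in g_exact))
        assert num / den <= 0.05

    def test_enumeration_probabilities_sum_to_one(self):
        P, E, policy, reward = toy_problem(seed=5)
        eps = enumerate_episodes(P, E, policy, reward)
        assert len(eps) == 8
        assert sum(p for _, p, _ in eps) == pytest.approx(1.0)

    def test_baseline_keeps_estimator_unbiased_and_cuts_variance(self):
        """On the exhaustive T=2 toy: mean gradients with and without the
        baseline both converge to the exact gradient, and the baseline
        strictly reduces estimator variance."""
        P, E, policy, reward = toy_problem(seed=7, T=2)
        g_exact = np.concatenate([g.ravel() for g in
                                  finite_difference_gradient(P, E, policy, reward)])
        ests = {True: [], False: []}
        for k in range(400):
            rng = np.random.default_rng(1000 + k)
            episodes = sample_episodes(P, E, policy, 10, rng)
            masks = np.stack([ep.actions for ep in episodes]).astype(float)
            for ep, r in zip(episodes, reward.reward_for_masks(masks)):
                ep.reward = float(r)
            from erandet.rl_selector import reinforce_gradient
            for ub in (True, False):
                g = reinforce_gradient(episodes, policy, use_baseline=ub)
                ests[ub].append(np.concatenate([a.ravel() for a in g]))
        for ub in (True, False):
            mean = np.mean(ests[ub], axis=0)
            se = np.std(ests[ub], axis=0) / np.sqrt(len(ests[ub]))
            assert np.all(np.abs(mean - g_exact) <= 4 * se + 1e-4)
        var_with = np.var(np.stack(ests[True]), axis=0).sum()
        var_without = np.var(np.stack(ests[False]), axis=0).sum()
        assert var_with < var_without
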