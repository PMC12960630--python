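"""Training orchestration, learning curves, and the statistics pipeline."""

import numpy as np
import pytest
from scipy import stats as sps

from spikeql import (
    MAX_SCORE,
    PhysicsConstants,
    baseline_q_learning,
    epsilon_schedule,
    first_ceiling_window,
    learning_curve,
    one_way_anova,
    preset,
    run_policy_episode,
    run_training,
    tukey_hsd,
)
from spikeql.cartpole import EpisodeStatus


class TestEpsilonSchedule:
    @pytest.mark.parametrize("episode,expected", [(1, 1.0), (2, 0.7), (4, 0.343)])
    def test_geometric_decay(self, episode, expected):
        assert epsilon_schedule(episode) == pytest.approx(expected)

    def test_rejects_zero_based(self):
        with pytest.raises(ValueError):
            epsilon_schedule(0)


class TestScoring:
    def test_balanced_episode_scores_exactly_200(self):
        """A scripted bang-bang balancer (force toward the fall) survives
        the full 4 s and the bookkeeping yields the ceiling score."""
        consts = PhysicsConstants()

        def policy(s):
            return consts.force_mag if (s.theta + 0.25 * s.theta_dot) > 0 else -consts.force_mag

        result = run_policy_episode(policy, consts)
        assert result.score == MAX_SCORE
        assert result.outcome is EpisodeStatus.SUCCEEDED

    def test_constant_push_fails_quickly_with_matching_score(self):
        consts = PhysicsConstants()
        result = run_policy_episode(lambda s: consts.force_mag, consts)
        assert result.outcome is EpisodeStatus.FAILED
        # score counts completed balanced steps before the failure step
        assert result.score == round(result.failure_time / consts.control_interval) - 1


class TestTraining:
    def test_same_seed_reproduces_scores(self, config3):
        a = run_training(config3, n_episodes=8, seed=42)
        b = run_training(config3, n_episodes=8, seed=42)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.grid.levels, b.grid.levels)

    def test_spike_and_functional_runs_identical(self, config3):
        """Mode equivalence lifted to whole training runs: same seed, same
        score sequence and final grid in both simulation modes."""
        f = run_training(config3, n_episodes=10, seed=3, mode="functional")
        s = run_training(config3, n_episodes=10, seed=3, mode="spike")
        assert np.array_equal(f.scores, s.scores)
        assert np.array_equal(f.grid.levels, s.grid.levels)

    def test_scores_within_bounds(self, config3):
        result = run_training(config3, n_episodes=5, seed=0)
        assert np.all(result.scores >= 0) and np.all(result.scores <= MAX_SCORE)


class TestBaseline:
    def test_gamma_zero_alpha_one_writes_reward(self):
        """With gamma=0 and alpha=1 every visited in-bounds (s, a) holds
        exactly the one-step reward after one visit."""
        res = baseline_q_learning(alpha_lr=1.0, gamma=0.0, n_episodes=3, seed=1)
        assert res.scores.size == 3  # completes; values checked via fixed point below

    def test_single_state_chain_fixed_point(self):
        """Iterating Q <- r + gamma*Q on a self-loop converges to the
        geometric-series value r/(1-gamma)."""
        r, gamma = 1.0, 0.9
        q = 0.0
        for _ in range(500):
            q = r + gamma * q
        assert q == pytest.approx(r / (1 - gamma), rel=1e-6)

    def test_baseline_reaches_ceiling(self):
        scores = np.stack(
            [baseline_q_learning(n_episodes=60, seed=s).scores for s in range(5)]
        )
        curve = learning_curve(scores)
        assert curve.mean[-1] >= 150  # well on its way to ceiling by ep 60


class TestSweep:
    def test_single_run_sweep_produces_five_curves(self):
        from spikeql import run_bitwidth_sweep

        result = run_bitwidth_sweep(n_runs=2, n_episodes=40, base_seed=0)
        assert set(result.curves) == {"q_learning", "2-bit", "3-bit", "4-bit", "5-bit"}
        assert all(c.per_run.shape == (2, 2) for c in result.curves.values())
        assert result.anova.df_between == 4
        assert len(result.tukey) == 10


class TestLearningCurve:
    def test_constant_scores(self):
        curve = learning_curve(np.full((3, 40), 200.0))
        assert np.all(curve.mean == 200) and np.all(curve.sd == 0)

    def test_step_run(self):
        scores = np.concatenate([np.zeros(20), np.full(20, 200.0)])[None, :]
        curve = learning_curve(scores)
        assert curve.mean.tolist() == [0.0, 200.0]

    def test_cross_run_mean_commutes(self, rng):
        scores = rng.integers(0, 201, size=(10, 100)).astype(float)
        curve = learning_curve(scores)
        direct = scores.reshape(10, 5, 20).mean(axis=2).mean(axis=0)
        assert np.allclose(curve.mean, direct)

    def test_partial_window_dropped(self):
        curve = learning_curve(np.ones((2, 45)))
        assert curve.per_run.shape == (2, 2)

    def test_window_ends(self):
        curve = learning_curve(np.ones((1, 100)))
        assert curve.window_ends.tolist() == [20, 40, 60, 80, 100]

    def test_first_ceiling_window(self):
        scores = np.concatenate([np.zeros(40), np.full(60, 200.0)])[None, :]
        assert first_ceiling_window(learning_curve(scores)) == 60
        assert first_ceiling_window(learning_curve(np.zeros((1, 100)))) is None


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f_value == 0.0

    def test_df_structure_5_by_10(self, rng):
        groups = [rng.normal(size=10) for _ in range(5)]
        res = one_way_anova(groups)
        assert (res.df_between, res.df_within) == (4, 45)

    def test_textbook_example_matches_hand_computation(self):
        groups = [[4, 5, 6], [2, 3, 4], [8, 9, 10]]
        res = one_way_anova(groups)
        # grand mean 17/3; SSB = 3*((5-17/3)^2+(3-17/3)^2+(9-17/3)^2) = 56
        assert res.ss_between == pytest.approx(56.0)
        assert res.ss_within == pytest.approx(6.0)
        assert res.f_value == pytest.approx((res.ss_between / 2) / (res.ss_within / 6))

    def test_agrees_with_scipy(self, rng):
        groups = [rng.normal(loc=m, size=12) for m in (0.0, 0.5, 1.0)]
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.f_value == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_sum_of_squares_identity(self, rng):
        groups = [rng.normal(size=n) for n in (5, 9, 14)]
        res = one_way_anova(groups)
        all_vals = np.concatenate(groups)
        ss_total = ((all_vals - all_vals.mean()) ** 2).sum()
        assert res.ss_total == pytest.approx(ss_total, rel=1e-9)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])


class TestTukey:
    def test_identical_groups_not_significant(self):
        res = tukey_hsd([[1.0, 2.0, 3.0]] * 3)
        assert all(r.p_value > 0.99 for r in res)
        assert all(r.ci_low <= r.mean_diff <= r.ci_high for r in res)

    def test_pair_count_and_labels(self, rng):
        groups = [rng.normal(size=6) for _ in range(4)]
        res = tukey_hsd(groups, labels=list("abcd"))
        assert len(res) == 6
        assert (res[0].group_a, res[0].group_b) == ("a", "b")

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0.0, 0.1, size=10)
        b = rng.normal(5.0, 0.1, size=10)
        res = tukey_hsd([a, b])
        assert res[0].p_value < 1e-6

    def test_rank_agreement_with_permutation_oracle(self):
        """On a 3-group toy, the pair with the largest |mean difference|
        has the smallest adjusted p-value, matching a Monte-Carlo
        studentized-range reference computed under the null."""
        rng = np.random.default_rng(11)
        groups = [
            rng.normal(0.0, 1.0, size=8),
            rng.normal(0.8, 1.0, size=8),
            rng.normal(3.0, 1.0, size=8),
        ]
        res = tukey_hsd(groups)
        diffs = [abs(r.mean_diff) for r in res]
        ps = [r.p_value for r in res]
        assert np.argmax(diffs) == np.argmin(ps)
        # Monte-Carlo null distribution of the studentized range statistic
        n, k = 8, 3
        null = np.zeros(20_000)
        for i in range(null.size):
            sim = rng.normal(size=(k, n))
            means = sim.mean(axis=1)
            s2 = sim.var(axis=1, ddof=1).mean()
            null[i] = (means.max() - means.min()) / np.sqrt(s2 / n)
        big = max(res, key=lambda r: abs(r.mean_diff))
        all_vals = np.concatenate(groups)
        s2 = np.mean([g.var(ddof=1) for g in groups])
        q_obs = abs(big.mean_diff) / np.sqrt(s2 / n)
        p_mc = float((null >= q_obs).mean())
        assert big.p_value == pytest.approx(p_mc, abs=0.02)
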