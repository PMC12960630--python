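"""Architecture assembly: config invariants, policy circuits, transitions."""

import numpy as np
import pytest
from scipy import stats as sps

from spikeql import (
    NetworkConfig,
    PolicyDraw,
    PulseSignal,
    QTableGrid,
    SpikeTrain,
    draw_policy,
    exploitation_winner,
    exploration_gate,
    gamma_population,
    one_hot_encode,
    preset,
    rate_encode,
    select_action,
    step_transition,
)
from spikeql.network import UpdateTable, load_config


class TestNetworkConfig:
    def test_presets_valid_all_bitwidths(self, config):
        assert config.max_level == 2**config.bits
        assert config.tau_alpha <= config.tau_d

    def test_rejects_uncalibrated_penalty(self):
        # floor(1000 * 0.005) = 5 != 8
        with pytest.raises(ValueError, match="penalty calibration"):
            preset(3, f_penalty=1000.0)

    def test_rejects_alpha_window_exceeding_delay(self):
        with pytest.raises(ValueError, match="tau_alpha"):
            preset(3, tau_alpha=0.006)

    def test_action_rate_endpoints_3bit(self, config3):
        assert config3.action_rate(1) == pytest.approx(201.0)
        assert config3.action_rate(8) == pytest.approx(1610.0)

    def test_action_rate_floor_identity(self, config):
        for k in range(1, config.max_level + 1):
            assert int(config.action_rate(k) * config.tau_alpha) == k

    def test_action_rate_out_of_range(self, config3):
        with pytest.raises(ValueError):
            config3.action_rate(9)

    def test_yaml_roundtrip(self, tmp_path, config3):
        import yaml

        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(config3.to_dict()))
        loaded = load_config(path)
        assert loaded == config3


class TestGridTopology:
    def test_cartpole_grid_is_19_by_2(self, config3):
        grid = QTableGrid.from_config(config3)
        assert (grid.p, grid.q) == (19, 2)
        assert grid.n_synapses == 38

    def test_dimensions_fixed_after_construction(self, config3):
        grid = QTableGrid.from_config(config3)
        before = grid.levels.shape
        draw = PolicyDraw(explore=False, x=1)
        step_transition(grid, 1, 1, 2, False, draw, config3)
        assert grid.levels.shape == before

    def test_frame_snapshot_labels(self, config3):
        frame = QTableGrid.from_config(config3).to_frame()
        assert list(frame.index[:2]) == ["s_1", "s_2"]
        assert list(frame.columns) == ["a_1", "a_2"]


class TestOneHot:
    def test_single_high_element(self):
        v = one_hot_encode(3, 19)
        assert v.sum() == 1 and v[2] == 1

    def test_failure_state_encodes(self):
        assert one_hot_encode(19, 19)[18] == 1

    def test_degenerate_single_state(self):
        assert one_hot_encode(1, 1).tolist() == [1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            one_hot_encode(20, 19)


class TestPolicyCircuits:
    def test_winner_is_argmax(self):
        assert exploitation_winner(np.array([3, 5])) == 2

    def test_tie_breaks_low_by_default(self):
        assert exploitation_winner(np.array([4, 4])) == 1

    def test_tie_break_draw_selects_among_tied(self):
        row = np.array([4, 4])
        winners = {exploitation_winner(row, tb) for tb in range(4)}
        assert winners == {1, 2}

    def test_exploitation_has_no_suppression(self):
        mask = exploration_gate(PolicyDraw(explore=False, x=1), 2)
        assert mask.tolist() == [0, 0]

    def test_exploration_suppresses_all_but_x(self):
        assert exploration_gate(PolicyDraw(explore=True, x=1), 2).tolist() == [0, 1]
        assert exploration_gate(PolicyDraw(explore=True, x=2), 2).tolist() == [1, 0]

    def test_select_action_single_active_train(self, config3):
        dt = config3.dt
        trains = [
            SpikeTrain.empty(0.0, 0.005, dt),
            rate_encode(800.0, 0.0, 0.005, dt),
        ]
        assert select_action(trains, PulseSignal.pulse(0.0, 0.005)) == 2

    def test_select_action_agrees_with_argmax(self, config3, rng):
        """With no exploration, counting spikes of WTA-gated trains equals
        the direct argmax of the Q row (100 random rows)."""
        window = PulseSignal.pulse(0.0, config3.tau_d)
        for _ in range(100):
            row = rng.integers(1, 9, size=2)
            winner = exploitation_winner(row)
            trains = [
                rate_encode(
                    config3.action_rate(int(row[m])) if (m + 1) == winner else 0.0,
                    0.0,
                    config3.tau_d,
                    config3.dt,
                )
                for m in range(2)
            ]
            assert select_action(trains, window) == winner

    def test_policy_statistics(self):
        """epsilon_pi frequency within 3 sigma of epsilon; X uniform over
        actions (chi-square at the 1% level); 10,000 draws."""
        rng = np.random.default_rng(7)
        eps, n, q = 0.3, 10_000, 4
        draws = [draw_policy(rng, eps, q) for _ in range(n)]
        frac = np.mean([d.explore for d in draws])
        sigma = np.sqrt(eps * (1 - eps) / n)
        assert abs(frac - eps) < 3 * sigma
        counts = np.bincount([d.x for d in draws], minlength=q + 1)[1:]
        assert sps.chisquare(counts).pvalue > 0.01


class TestGammaPopulation:
    def test_winner_rate_scaled_by_gamma(self, config3):
        train = gamma_population(np.array([3, 8]), config3)
        # floor(0.99 * 1610 * 0.005) = 7 spikes in the alpha window
        assert len(train) == 7

    def test_zero_gamma_gives_empty_train(self):
        cfg = preset(3, gamma=0.0)
        assert len(gamma_population(np.array([5, 2]), cfg)) == 0

    def test_tie_uses_same_level_either_way(self, config3):
        # tied maxima share the level, so the gamma rate is tie-invariant
        t = gamma_population(np.array([6, 6]), config3)
        assert len(t) == int(0.99 * config3.action_rate(6) * config3.tau_alpha)


class TestStepTransition:
    def test_locality_single_synapse_changes(self, config3, rng):
        grid = QTableGrid.from_config(config3)
        for _ in range(50):
            before = grid.levels.copy()
            prev, new = rng.integers(1, 20, size=2)
            action = int(rng.integers(1, 3))
            draw = draw_policy(rng, 0.5, 2)
            step_transition(grid, int(prev), action, int(new), new == 19, draw, config3)
            assert (grid.levels != before).sum() <= 1
            changed = np.argwhere(grid.levels != before)
            if changed.size:
                assert tuple(changed[0]) == (prev - 1, action - 1)

    def test_failure_transition_clamps_low(self, config3):
        grid = QTableGrid.from_config(config3)
        draw = PolicyDraw(explore=False, x=1)
        step_transition(grid, 18, 1, 19, True, draw, config3)
        assert grid.level(18, 1) == 1

    def test_first_transition_changes_little(self, config3):
        # all synapses at the ceiling: reward + gamma spikes nearly cancel
        # the depression spikes, so the visited synapse moves at most 1 step
        grid = QTableGrid.from_config(config3)
        draw = PolicyDraw(explore=False, x=1)
        step_transition(grid, 8, 1, 9, False, draw, config3)
        assert abs(grid.level(8, 1) - 8) <= 1

    def test_exploration_forces_selected_action(self, config3):
        grid = QTableGrid.from_config(config3)
        grid.set_level(2, 1, 1)  # a_2 has the higher Q at s_2
        draw = PolicyDraw(explore=True, x=1)
        _, action, _ = step_transition(grid, 1, 1, 2, False, draw, config3)
        assert action == 1  # X overrides the WTA winner

    def test_invalid_indices_rejected(self, config3):
        grid = QTableGrid.from_config(config3)
        draw = PolicyDraw(explore=False, x=1)
        with pytest.raises(ValueError):
            step_transition(grid, 0, 1, 2, False, draw, config3)
        with pytest.raises(ValueError):
            step_transition(grid, 1, 3, 2, False, draw, config3)

    def test_spike_mode_returns_waveform_bundle(self, config3):
        grid = QTableGrid.from_config(config3)
        draw = PolicyDraw(explore=False, x=1)
        _, _, wf = step_transition(
            grid, 1, 2, 2, False, draw, config3, mode="spike", capture=True
        )
        assert {"R", "P", "alpha", "gamma"} <= set(wf)
        assert any(k.startswith("ET_") for k in wf)


class TestModeEquivalence:
    def test_spike_equals_functional_on_random_transitions(self, config, rng):
        """Spike-level pipeline and the analytic functional route give
        bit-identical grids on 200 random transitions (all bit-widths,
        random levels, outcomes, and sojourn lengths)."""
        n_cases = 50  # per bit-width fixture; 200 across the session
        table = UpdateTable(config)
        for _ in range(n_cases):
            q0 = int(rng.integers(1, config.max_level + 1))
            nm = int(rng.integers(1, config.max_level + 1))
            fail = bool(rng.random() < 0.3)
            k = int(rng.integers(1, 6))
            gf = QTableGrid.from_config(config)
            gs = QTableGrid.from_config(config)
            for g in (gf, gs):
                g.set_level(1, 1, q0)
                g.set_level(2, 1, nm)
                g.set_level(2, 2, 1)
            draw = draw_policy(rng, 0.3, 2)
            step_transition(gf, 1, 1, 2, fail, draw, config, mode="functional",
                            table=table, sojourn_steps=k)
            step_transition(gs, 1, 1, 2, fail, draw, config, mode="spike",
                            sojourn_steps=k)
            assert np.array_equal(gf.levels, gs.levels), (q0, nm, fail, k)
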