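"""World-model learning and forward-sampling planning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeplan import (
    CORRECT,
    INCORRECT,
    ModelParams,
    action,
    colour,
    goal_weight_delta,
    init_weights,
    learn_trial,
    load_weights,
    planning_cycle,
    readout,
    save_weights,
    spikes_to_frame,
    stdp_apply,
    stdp_delta,
    update_goal_weights,
)
from conftest import build_chain_weights


class TestStdpRule:
    def test_zero_increment_at_fixed_point(self):
        c = 0.67
        assert stdp_delta(-np.log(c), 1, 1, zeta=0.96, c=c) == pytest.approx(0.0)

    def test_depression_without_pre_spike(self):
        assert stdp_delta(0.3, 1, 0, zeta=0.96, c=0.67) == pytest.approx(-0.96 * 0.67)

    def test_gated_by_post_spike(self):
        assert stdp_delta(1.7, 0, 1, zeta=0.96, c=0.67) == 0.0

    def test_potentiation_from_zero(self):
        assert stdp_delta(0.0, 1, 1, zeta=0.96, c=0.67) == pytest.approx(0.96 * 0.33)

    @settings(max_examples=25, deadline=None)
    @given(
        zeta=st.floats(0.1, 1.0),
        c=st.floats(0.1, 0.99),
        w0=st.floats(-0.9, 0.0),
    )
    def test_persistent_cofiring_converges_monotonically(self, zeta, c, w0):
        target = -np.log(c)
        w, prev = w0, -np.inf
        for _ in range(5000):
            prev, w = w, stdp_apply(w, 1, 1, zeta, c, floor=-6.0)
            assert w >= prev - 1e-12  # monotone from below
        assert abs(w - target) < 1e-3

    def test_bounds_respected(self):
        # deep depression is floored; potentiation never exceeds -ln(c)
        w = 0.0
        for _ in range(100):
            w = stdp_apply(w, 1, 0, 0.96, 0.67, floor=-0.9)
        assert w == pytest.approx(-0.9)
        w = stdp_apply(w, 1, 1, 0.96, 0.67, floor=-0.9)
        assert w <= -np.log(0.67) + 1e-12


class TestGoalRule:
    def test_increment_from_zero(self):
        d = goal_weight_delta(0.0, +1, 1, 1, eta=0.008, w_max=0.5)
        assert d == pytest.approx(0.008)

    def test_bound_factor_vanishes_at_wmax(self):
        assert goal_weight_delta(0.5, +1, 1, 1, 0.008, 0.5) == 0.0
        assert goal_weight_delta(-0.5, -1, 1, 1, 0.008, 0.5) == 0.0

    def test_eligibility_and_goal_gates(self):
        assert goal_weight_delta(0.1, +1, 0, 1, 0.008, 0.5) == 0.0
        assert goal_weight_delta(0.1, +1, 1, 0, 0.008, 0.5) == 0.0

    def test_invalid_pseudo_reward(self):
        with pytest.raises(ValueError):
            goal_weight_delta(0.0, 0, 1, 1, 0.008, 0.5)

    def test_out_of_bound_entry_raises(self):
        with pytest.raises(ValueError, match="w_max"):
            goal_weight_delta(0.6, +1, 1, 1, 0.008, 0.5)

    def test_weights_stay_bounded_under_random_updates(self, params, rng):
        weights = init_weights(params, rng)
        units = frozenset(range(40))
        for _ in range(10_000):
            m = 1 if rng.random() < 0.5 else -1
            update_goal_weights(weights, units, m, goal=0)
        assert np.abs(weights.W_goal_assoc).max() <= params.w_max + 1e-12

    def test_silent_units_and_inactive_goal_untouched(self, params, rng):
        weights = init_weights(params, rng)
        before = weights.W_goal_assoc.copy()
        update_goal_weights(weights, frozenset({1, 2, 3}), +1, goal=0)
        # inactive goal row identical; silent units of the active row identical
        np.testing.assert_array_equal(weights.W_goal_assoc[1], before[1])
        untouched = [k for k in range(params.n_assoc) if k not in {1, 2, 3}]
        np.testing.assert_array_equal(
            weights.W_goal_assoc[0, untouched], before[0, untouched]
        )
        assert np.all(weights.W_goal_assoc[0, [1, 2, 3]] > before[0, [1, 2, 3]])

    def test_repeated_reinforcement_saturates_at_bound(self, params, rng):
        weights = init_weights(params, rng)
        for _ in range(5000):
            update_goal_weights(weights, frozenset({7}), +1, goal=0)
        w = weights.W_goal_assoc[0, 7]
        assert w <= params.w_max and w == pytest.approx(params.w_max, abs=1e-6)


class TestReadout:
    def test_unique_maximum(self, rng):
        spikes = np.zeros((15, 10))
        spikes[:5, 4] = 1.0  # action 2 (unit 4), five spikes
        spikes[5, 3] = 1.0
        ev = readout(spikes, "action", rng)
        assert ev.kind == "action" and ev.index == 2

    def test_empty_category_returns_none(self, rng):
        spikes = np.zeros((15, 10))
        spikes[:, 0] = 1.0  # all spikes on a colour unit
        assert readout(spikes, "action", rng) is None

    def test_tie_broken_uniformly(self, rng):
        spikes = np.zeros((6, 10))
        spikes[:3, 8] = 1.0  # feedback 'correct'
        spikes[3:, 9] = 1.0  # feedback 'incorrect'
        picks = [readout(spikes, "feedback", rng).index for _ in range(4000)]
        frac = np.mean([p == 1 for p in picks])
        assert abs(frac - 0.5) < 4 * 0.5 / np.sqrt(4000)

    def test_unknown_category_raises(self, rng):
        with pytest.raises(ValueError):
            readout(np.zeros((15, 10)), "colour?", rng)


class TestPlanningCycle:
    def test_structure(self, params, rng):
        weights = init_weights(params, rng)
        cyc = planning_cycle(weights, colour(1), 0, params, rng)
        assert cyc.assoc_spikes.shape == (params.n_steps, params.n_assoc)
        assert np.all(cyc.assoc_spikes.sum(axis=1) == 1.0)
        assert np.all(cyc.out_spikes.sum(axis=1) == 1.0)
        assert 0.0 <= cyc.mean_entropy <= 1.0
        assert cyc.fired_free <= cyc.fired_units

    def test_untrained_model_is_maximally_uncertain(self, rng):
        params = ModelParams(noise_in_planning=False, init_sd=0.0)
        weights = init_weights(params, rng)
        cyc = planning_cycle(weights, colour(2), 0, params, rng)
        assert cyc.mean_entropy > 0.95

    def test_never_mutates_weights(self, params, rng):
        weights = init_weights(params, rng)
        snapshot = weights.copy()
        planning_cycle(weights, colour(1), 0, params, rng)
        for name in ("W_in_assoc", "W_goal_assoc", "W_assoc_assoc", "W_assoc_out"):
            np.testing.assert_array_equal(getattr(weights, name), getattr(snapshot, name))

    def test_deterministic_chain_readout(self, params, rng):
        weights = build_chain_weights(params, colour_idx=1, action_idx=3, outcome_correct=True)
        quiet = ModelParams(noise_in_planning=False)
        for _ in range(5):
            cyc = planning_cycle(weights, colour(1), 0, quiet, rng)
            assert cyc.readout_action == action(3)
            assert cyc.readout_outcome == CORRECT
            assert cyc.mean_entropy < 0.1

    def test_invalid_inputs(self, params, rng):
        weights = init_weights(params, rng)
        with pytest.raises(ValueError):
            planning_cycle(weights, action(1), 0, params, rng)
        with pytest.raises(ValueError):
            planning_cycle(weights, colour(1), 5, params, rng)


class TestLearning:
    def test_recurrent_diagonal_stays_zero(self, params, rng):
        weights = init_weights(params, rng)
        for i in range(120):
            learn_trial(
                weights,
                colour(i % 3 + 1),
                action(i % 5 + 1),
                CORRECT if i % 2 else INCORRECT,
                i % 2,
                params,
                rng,
            )
        assert np.abs(np.diag(weights.W_assoc_assoc)).max() == 0.0

    def test_weights_stay_within_stdp_bounds(self, params, rng):
        weights = init_weights(params, rng)
        for i in range(60):
            learn_trial(weights, colour(1), action(2), INCORRECT, 0, params, rng)
        cap = -np.log(params.c) + 1e-9
        assert weights.W_in_assoc.max() <= cap
        assert weights.W_in_assoc.min() >= params.stdp_floor_in - 1e-9
        assert weights.W_assoc_assoc.max() <= cap
        assert weights.W_assoc_out.min() >= params.stdp_floor_out - 1e-9

    def test_trained_action_dominates_planning_readout(self, params):
        # the central closed loop: repeat one contingency, then plan; the
        # trained action's readout frequency must reach 0.8, estimated over
        # several independent realisations to tame single-run variance
        rates = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            weights = init_weights(params, rng)
            for _ in range(60):
                learn_trial(weights, colour(1), action(5), CORRECT, 0, params, rng)
            hits = sum(
                planning_cycle(weights, colour(1), 0, params, rng).readout_action
                == action(5)
                for _ in range(100)
            )
            rates.append(hits / 100)
        assert np.mean(rates) >= 0.8

    def test_goal_weights_untouched_by_replay(self, params, rng):
        weights = init_weights(params, rng)
        before = weights.W_goal_assoc.copy()
        learn_trial(weights, colour(1), action(1), CORRECT, 0, params, rng)
        np.testing.assert_array_equal(weights.W_goal_assoc, before)

    def test_returns_nonempty_eligibility_trace(self, params, rng):
        weights = init_weights(params, rng)
        _, fired = learn_trial(weights, colour(2), action(4), INCORRECT, 1, params, rng)
        assert 1 <= len(fired) <= params.n_steps

    def test_invalid_event_kinds(self, params, rng):
        weights = init_weights(params, rng)
        with pytest.raises(ValueError):
            learn_trial(weights, action(1), action(1), CORRECT, 0, params, rng)
        with pytest.raises(ValueError):
            learn_trial(weights, colour(1), colour(2), CORRECT, 0, params, rng)


class TestBranching:
    def test_two_trained_continuations_both_sampled(self, params, rng):
        # miniature generativity check on a hand-built fork
        weights = build_chain_weights(params, colour_idx=1, action_idx=3)
        # graft a second action branch: unit 20..24 also reachable from unit 4
        for t, u in enumerate(range(20, 25)):
            weights.W_assoc_assoc[(4 if t == 0 else u - 1), u] = 5.0
            weights.W_assoc_out[u, 6] = 5.0  # action 4
        seen = set()
        for _ in range(60):
            cyc = planning_cycle(weights, colour(1), None, params, rng)
            if cyc.readout_action is not None:
                seen.add(cyc.readout_action.index)
        assert {3, 4} <= seen


class TestSerialization:
    def test_roundtrip(self, params, rng, tmp_path):
        weights = init_weights(params, rng)
        learn_trial(weights, colour(1), action(2), CORRECT, 0, params, rng)
        path = tmp_path / "weights.npz"
        save_weights(weights, path, extra_meta={"seed": 7})
        loaded = load_weights(path)
        for name in ("W_in_assoc", "W_goal_assoc", "W_assoc_assoc", "W_assoc_out", "W_explore"):
            np.testing.assert_array_equal(getattr(weights, name), getattr(loaded, name))
        assert loaded.zeta == weights.zeta and loaded.c == weights.c

    def test_raster_export_is_tidy(self, params, rng):
        weights = init_weights(params, rng)
        cyc = planning_cycle(weights, colour(1), 0, params, rng)
        frame = spikes_to_frame(cyc)
        assert set(frame.columns) == {"step", "layer", "unit"}
        assert len(frame) == 2 * params.n_steps  # one assoc + one output spike per step
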