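"""Pathfinder wrapper selection: cost identity, update algebra, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fepfa import (
    LabeledFeatureMatrix,
    PfaConfig,
    PfaState,
    SelectionMask,
    binarize,
    fitness,
    run_pfa,
)
from fepfa.pfa import follower_update, pathfinder_update


class _StubRng:
    """Deterministic stand-in for the swarm RNG.

    ``uniform_values`` are returned (broadcast to the requested size) by
    successive uniform() calls; integers() always returns 0.
    """

    def __init__(self, uniform_values):
        self.uniform_values = list(uniform_values)

    def uniform(self, low=0.0, high=1.0, size=None):
        v = self.uniform_values.pop(0)
        return np.full(size, v) if size is not None else v

    def integers(self, n):
        return 0


def _state(positions, leader_idx=0, leader_prev=None, iteration=1, rng=None):
    positions = np.asarray(positions, dtype=float)
    return PfaState(
        positions=positions,
        leader_idx=leader_idx,
        leader_prev=positions[leader_idx].copy() if leader_prev is None else np.asarray(leader_prev, float),
        iteration=iteration,
        best_position=positions[leader_idx].copy(),
        best_cost=np.inf,
        rng=rng,
    )


class TestBinarize:
    def test_all_high_full_mask(self):
        assert binarize(np.full(5, 0.9)).selected.all()

    def test_all_low_selects_argmax(self):
        mask = binarize(np.array([0.1, 0.3, 0.2]))
        assert np.array_equal(mask.selected, [False, True, False])

    def test_strict_threshold(self):
        mask = binarize(np.array([0.4, 0.6, 0.5]))
        assert np.array_equal(mask.selected, [False, True, False])

    def test_tie_goes_to_lowest_index(self):
        mask = binarize(np.array([0.2, 0.2, 0.2]))
        assert np.array_equal(mask.selected, [True, False, False])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.5, 1.2]))


class TestFitness:
    def test_eq_identity_exact(self, recovery_data, rng):
        data, _ = recovery_data
        cfg = PfaConfig(seed=1)
        for _ in range(5):
            mask = SelectionMask(rng.uniform(size=200) > 0.4)
            rec = fitness(mask, data, cfg)
            resid = rec.cost - cfg.phi_alpha * rec.error - cfg.phi_beta * (
                rec.n_selected / data.n_features
            )
            assert abs(resid) < 1e-12
            assert rec.error == 1.0 - rec.accuracy

    def test_perfect_separation_costs_selection_fraction_only(self):
        # two far-apart classes: KNN accuracy 1, so cost = 0.014 * 1
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(50, 0.1, (20, 3))])
        data = LabeledFeatureMatrix(x, np.repeat([0, 1], 20))
        rec = fitness(SelectionMask(np.ones(3, bool)), data, PfaConfig(seed=0))
        assert rec.accuracy == 1.0
        assert rec.cost == pytest.approx(0.014, abs=1e-15)

    def test_weighted_composition_example(self):
        # error 0.1 with half of features selected composes to 0.101
        assert 0.94 * 0.1 + 0.014 * 0.5 == pytest.approx(0.101)

    def test_cv5_scheme_runs(self, recovery_data):
        data, truth = recovery_data
        cfg = PfaConfig(eval_scheme="cv5", seed=1)
        rec = fitness(SelectionMask(truth.informative_mask), data, cfg)
        assert 0.0 <= rec.accuracy <= 1.0


class TestUpdates:
    def test_leader_stationary_when_randomness_zero(self):
        state = _state([[0.3, 0.7], [0.2, 0.2]], rng=_StubRng([0.0, 0.0]))
        new = pathfinder_update(state, PfaConfig(max_iter=10))
        assert np.allclose(new, [0.3, 0.7])

    def test_fluctuation_magnitude_at_final_iteration(self):
        # r3 = 0, u2 = 1 at k = k_max gives a shift of exactly e^-2
        state = _state([[0.5, 0.5], [0.1, 0.1]], iteration=10, rng=_StubRng([0.0, 1.0]))
        new = pathfinder_update(state, PfaConfig(max_iter=10))
        assert np.allclose(new - 0.5, np.exp(-2.0))

    def test_follower_stationary_when_randomness_zero(self):
        state = _state([[0.3, 0.7], [0.6, 0.1]], rng=_StubRng([0.0, 0.0, 0.0]))
        new = follower_update(state, 1, PfaConfig(max_iter=10), alpha=1.5, beta=1.5)
        assert np.allclose(new, [0.6, 0.1])

    def test_vibration_vanishes_at_last_iteration(self):
        # u1 = 1 would add the member distance, but (1 - k/k_max) kills it
        state = _state(
            [[0.3, 0.7], [0.6, 0.1]], iteration=10, rng=_StubRng([0.0, 0.0, 1.0])
        )
        new = follower_update(state, 1, PfaConfig(max_iter=10), alpha=1.5, beta=1.5)
        assert np.allclose(new, [0.6, 0.1])

    def test_coincident_swarm_is_fixed_point(self):
        pos = np.tile([0.4, 0.6], (3, 1))
        state = _state(pos, rng=_StubRng([0.5, 0.5, 0.9]))
        new = follower_update(state, 1, PfaConfig(max_iter=10), alpha=2.0, beta=2.0)
        assert np.allclose(new, [0.4, 0.6])

    def test_leader_not_a_follower(self):
        state = _state([[0.3, 0.7], [0.6, 0.1]], rng=_StubRng([0, 0, 0]))
        with pytest.raises(ValueError):
            follower_update(state, 0, PfaConfig(max_iter=10), alpha=1.0, beta=1.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(2, 5), st.integers(1, 8)),
            elements=st.floats(0, 1, allow_nan=False, width=32),
        ),
        st.integers(0, 2**31 - 1),
        st.integers(1, 10),
    )
    def test_updates_stay_in_unit_box(self, positions, seed, iteration):
        rng = np.random.default_rng(seed)
        cfg = PfaConfig(max_iter=10)
        state = _state(positions, iteration=iteration, rng=rng)
        state.leader_prev = rng.uniform(size=positions.shape[1])
        lead = pathfinder_update(state, cfg)
        assert np.all((lead >= 0) & (lead <= 1))
        foll = follower_update(state, 1, cfg, alpha=2.0, beta=2.0)
        assert np.all((foll >= 0) & (foll <= 1))


class TestRunPfa:
    @pytest.fixture(scope="class")
    def small_run(self, recovery_data):
        data, _ = recovery_data
        cfg = PfaConfig(swarm_size=8, max_iter=8, knn_k=5, seed=3)
        return run_pfa(data, cfg), cfg, data

    def test_history_non_increasing(self, small_run):
        (_, _, history), _, _ = small_run
        assert all(a >= b for a, b in zip(history, history[1:]))
        assert len(history) == 9  # initial best + one entry per iteration

    def test_final_cost_beats_all_features(self, small_run):
        (_, record, _), cfg, data = small_run
        all_rec = fitness(SelectionMask(np.ones(data.n_features, bool)), data, cfg)
        assert record.cost <= all_rec.cost

    def test_deterministic_under_seed(self, recovery_data):
        data, _ = recovery_data
        cfg = PfaConfig(swarm_size=5, max_iter=4, seed=9)
        m1, r1, h1 = run_pfa(data, cfg)
        m2, r2, h2 = run_pfa(data, cfg)
        assert np.array_equal(m1.selected, m2.selected)
        assert h1 == h2
        assert r1.cost == r2.cost

    def test_rejects_single_class(self):
        data = LabeledFeatureMatrix(np.random.default_rng(0).normal(size=(10, 4)), np.zeros(10, int))
        with pytest.raises(ValueError):
            run_pfa(data, PfaConfig(swarm_size=3, max_iter=2))
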