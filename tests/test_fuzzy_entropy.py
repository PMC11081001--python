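"""Fuzzy C-means and entropy-based refinement."""

import numpy as np
import pytest
from scipy.optimize import minimize

from fepfa import (
    SelectionMask,
    fcm_1d,
    fuzzy_entropy_score,
    make_gaussian_feature_data,
    refine_selection,
    shannon_entropy,
)
from fepfa.fuzzy_entropy import _fcm_memberships, fcm_objective


def reduced_objective(centers, values, e=2.0):
    """FCM objective with memberships optimized out (independent oracle).

    For fixed centers the optimal memberships are the closed-form update, so
    J(c) = sum_i (sum_j D_ij^{-2/(e-1)})^{-(e-1)}.
    """
    d2 = (values[:, None] - np.asarray(centers)[None, :]) ** 2
    d2 = np.maximum(d2, 1e-300)
    inner = (d2 ** (-1.0 / (e - 1.0))).sum(axis=1)
    return float((inner ** (-(e - 1.0))).sum())


class TestShannonEntropy:
    def test_degenerate_distribution(self):
        assert shannon_entropy(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_uniform_four(self):
        assert shannon_entropy(np.full(4, 0.25)) == pytest.approx(np.log(4))

    def test_fair_coin(self):
        assert shannon_entropy(np.array([0.5, 0.5])) == pytest.approx(np.log(2))

    def test_base_conversion(self):
        assert shannon_entropy(np.array([0.5, 0.5]), base=2) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [[0.5, 0.6], [-0.1, 1.1], [0.2, 0.2]])
    def test_invalid_distributions_rejected(self, bad):
        with pytest.raises(ValueError):
            shannon_entropy(np.array(bad))


class TestFcm1d:
    def test_two_well_separated_groups(self):
        fit = fcm_1d(np.array([0.0, 0.0, 10.0, 10.0]), C=2, e=2.0, seed=0)
        assert np.allclose(np.sort(fit.centers), [0.0, 10.0], atol=1e-3)
        own = fit.memberships.max(axis=1)
        assert np.all(own > 0.99)
        assert fit.converged

    def test_centers_minimize_reduced_objective(self):
        # brute-force multistart oracle on the reduced objective
        values = np.array([0.0, 0.1, 0.0, 9.9, 10.0, 10.1])
        fit = fcm_1d(values, C=2, e=2.0, seed=1)
        best = min(
            (
                minimize(reduced_objective, x0, args=(values,), method="Nelder-Mead")
                for x0 in ([0.0, 10.0], [2.0, 8.0], [5.0, 5.1])
            ),
            key=lambda r: r.fun,
        )
        assert np.allclose(np.sort(fit.centers), np.sort(best.x), atol=1e-3)
        assert fcm_objective(values, fit.centers, fit.memberships, 2.0) == pytest.approx(
            best.fun, abs=1e-6
        )

    def test_equidistant_point_membership_half(self):
        mu = _fcm_memberships(np.array([5.0]), np.array([0.0, 10.0]), e=2.0)
        assert np.allclose(mu, [[0.5, 0.5]])

    def test_point_on_center_gets_full_membership(self):
        mu = _fcm_memberships(np.array([10.0]), np.array([0.0, 10.0]), e=2.0)
        assert np.allclose(mu, [[0.0, 1.0]])

    def test_rows_stochastic_every_iteration(self):
        values = np.random.default_rng(2).normal(size=30)
        for k in range(1, 8):
            fit = fcm_1d(values, C=3, e=2.0, max_iter=k, seed=2)
            assert np.all(np.abs(fit.memberships.sum(axis=1) - 1.0) < 1e-9)

    def test_objective_non_increasing_across_iterations(self):
        values = np.random.default_rng(5).normal(size=40)
        objs = []
        for k in range(1, 12):
            fit = fcm_1d(values, C=3, e=2.0, max_iter=k, tol=0.0, seed=5)
            objs.append(fcm_objective(values, fit.centers, fit.memberships, 2.0))
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_constant_input_degenerate_not_raised(self):
        fit = fcm_1d(np.full(6, 3.3), C=2, e=2.0)
        assert fit.degenerate
        assert np.allclose(fit.memberships.sum(axis=1), 1.0)

    @pytest.mark.parametrize("kwargs", [dict(C=1), dict(e=1.0), dict(C=5)])
    def test_invalid_args(self, kwargs):
        with pytest.raises(ValueError):
            fcm_1d(np.arange(4.0), **{"C": 2, "e": 2.0, **kwargs})


class TestFuzzyEntropyScore:
    def test_bimodal_feature_ranked_ahead_of_noise(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 60)
        bimodal = np.where(labels == 0, -3.0, 3.0) + rng.normal(0, 0.3, 120)
        noise = rng.normal(size=120)
        s_bi = fuzzy_entropy_score(bimodal, labels, seed=0)
        s_noise = fuzzy_entropy_score(noise, labels, seed=0)
        assert s_bi.Fe < s_noise.Fe
        assert s_bi.crispness > s_noise.crispness
        assert s_bi.Fe < 0.05  # class-pure clusters

    def test_score_bounds(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(np.arange(4), 25)
        for _ in range(10):
            s = fuzzy_entropy_score(rng.normal(size=100), labels, seed=1)
            assert 0.0 <= s.Fe <= np.log(4) + 1e-12

    def test_degenerate_feature_scores_maximal_uncertainty(self):
        labels = np.repeat([0, 1], 5)
        s = fuzzy_entropy_score(np.zeros(10), labels, seed=0)
        assert s.Fe == pytest.approx(np.log(2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_entropy_score(np.arange(5.0), np.zeros(5, int))


class TestRefineSelection:
    @pytest.fixture(scope="class")
    def planted(self):
        return make_gaussian_feature_data(30, 4, 60, 12, 3.0, seed=2)

    def test_rho_one_is_identity_and_idempotent(self, planted):
        data, _ = planted
        mask = SelectionMask(np.ones(60, bool))
        out = refine_selection(data, mask, retain_fraction=1.0)
        assert np.array_equal(out.selected, mask.selected)

    def test_output_subset_of_input(self, planted):
        data, truth = planted
        rng = np.random.default_rng(1)
        mask = SelectionMask(rng.uniform(size=60) > 0.3)
        out = refine_selection(data, mask, retain_fraction=0.5, seed=0)
        assert np.all(out.selected <= mask.selected)
        assert out.n_selected == int(np.ceil(0.5 * mask.n_selected))

    def test_refinement_prefers_planted_features(self, planted):
        data, truth = planted
        mask = SelectionMask(np.ones(60, bool))
        out = refine_selection(data, mask, retain_fraction=12 / 60, seed=0)
        recall = (out.selected & truth.informative_mask).sum() / 12
        assert recall >= 0.9

    def test_published_dimension_reduction(self):
        data, _ = make_gaussian_feature_data(15, 4, 2048, 64, 3.0, seed=0)
        out = refine_selection(data, SelectionMask(np.ones(2048, bool)), seed=0)
        assert out.n_selected == 1467

    def test_bad_rho(self, planted):
        data, _ = planted
        with pytest.raises(ValueError):
            refine_selection(data, SelectionMask(np.ones(60, bool)), retain_fraction=0.0)
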