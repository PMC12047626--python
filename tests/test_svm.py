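"""Relative likelihood, objective criterion and conditional meta-d'."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grtmeta import (
    FittedModel,
    GroupModel,
    ParticipantParams,
    build_svm_curve,
    conditional_category_probs,
    conditional_distribution,
    fit_conditional_metad,
    objective_criterion,
    relative_likelihood,
)
from grtmeta.model import StimulusCondition


def make_group(mu_xc=1.0, mu_yc=1.0, mu_xi=-1.0, mu_yi=1.0, rhos=(0.0, 0.0, 0.0)):
    return GroupModel(
        means=np.array([[mu_xc, mu_yc], [mu_xi, mu_yi], [0.0, 0.0]]),
        correlations=np.array(rhos),
    )


def make_fitted(group, n_participants=3, judgment="TOT"):
    parts = [
        ParticipantParams(f"p{i}", 2.0, 0.5, 0.4 + 0.1 * i, -1.0, 1.0)
        for i in range(n_participants)
    ]
    return FittedModel(
        group=group, participants=parts, loglik=0.0, n_restarts_used=1,
        restart_logliks=[0.0], converged=[True], judgment=judgment,
    )


class TestRelativeLikelihood:
    def test_equal_means_give_unity(self):
        g = make_group(mu_yc=0.0, mu_yi=0.0)
        ys = np.linspace(-3, 3, 11)
        np.testing.assert_allclose(relative_likelihood(g, ys), 1.0, atol=1e-12)

    def test_density_ratio_closed_form(self):
        # both famous y-means 1: L(y) = exp(y - 1/2)
        g = make_group()
        assert relative_likelihood(g, 1.0) == pytest.approx(np.exp(0.5), rel=1e-12)

    def test_mixture_of_unequal_means(self):
        g = make_group(mu_yc=1.0, mu_yi=1.5)
        expected = 0.5 * np.exp(-0.5) + 0.5 * np.exp(-1.125)
        assert relative_likelihood(g, 0.0) == pytest.approx(expected, rel=1e-12)

    @given(
        mu_c=st.floats(0.1, 3.0),
        mu_i=st.floats(0.1, 3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_strictly_increasing_for_positive_means(self, mu_c, mu_i):
        g = make_group(mu_yc=mu_c, mu_yi=mu_i)
        ys = np.linspace(-5, 5, 201)
        L = relative_likelihood(g, ys)
        assert np.all(np.diff(L) > 0)


class TestObjectiveCriterion:
    @pytest.mark.parametrize("mu", [1.0, 2.0, 0.7])
    def test_equal_means_midpoint(self, mu):
        g = make_group(mu_yc=mu, mu_yi=mu)
        assert objective_criterion(g) == pytest.approx(mu / 2, abs=1e-8)

    def test_unequal_means_matches_bisection_oracle(self):
        g = make_group(mu_yc=1.0, mu_yi=1.5)

        def f(y):
            return 0.5 * np.exp(y - 0.5) + 0.5 * np.exp(1.5 * y - 1.125) - 1.0

        lo, hi = -5.0, 5.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert objective_criterion(g) == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_degenerate_model_rejected(self):
        g = make_group(mu_yc=0.0, mu_yi=0.0)
        with pytest.raises(ValueError, match="objective criterion"):
            objective_criterion(g)

    def test_unit_likelihood_at_root(self):
        g = make_group(mu_yc=0.8, mu_yi=1.9)
        y_star = objective_criterion(g)
        assert relative_likelihood(g, y_star) == pytest.approx(1.0, abs=1e-8)


class TestConditionalDistribution:
    def test_independence_ignores_y(self):
        g = make_group()
        for y in (-2.0, 0.0, 3.0):
            m, s = conditional_distribution(g, StimulusCondition.CORRECT_NAME, y)
            assert (m, s) == (1.0, 1.0)

    def test_regression_formula(self):
        g = make_group(rhos=(0.5, 0.5, 0.0))
        m, s = conditional_distribution(g, StimulusCondition.CORRECT_NAME, 2.0)
        assert m == pytest.approx(1.5)
        assert s == pytest.approx(np.sqrt(0.75))

    def test_category_probs_standard_normal(self):
        probs = conditional_category_probs((0.0, 1.0), -1.0, 1.0)
        np.testing.assert_allclose(
            probs, [0.1586552539, 0.6826894921, 0.1586552539], atol=1e-9
        )
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_category_probs_mirror_symmetry(self):
        a = conditional_category_probs((0.7, 1.3), -1.0, 1.0)
        b = conditional_category_probs((-0.7, 1.3), -1.0, 1.0)
        np.testing.assert_allclose(a, b[::-1], atol=1e-12)

    def test_inverted_criteria_rejected(self):
        with pytest.raises(ValueError, match="c_x1 < c_x2"):
            conditional_category_probs((0.0, 1.0), 1.0, -1.0)


class TestConditionalMetaD:
    def test_no_discriminability_gives_zero(self):
        g = make_group(mu_xc=0.5, mu_xi=0.5)  # identical x-distributions
        sdt = fit_conditional_metad(g, (-1.0, 1.0), 0.7)
        assert abs(sdt.meta_d) < 1e-6
        assert sdt.loss < 1e-10

    @pytest.mark.parametrize("y", [-1.0, 0.0, 1.7])
    def test_exact_recovery_under_independence(self, y):
        """With rho=0 the conditional model is itself an equal-variance
        SDT observer: meta-d' equals the mean separation exactly."""
        g = make_group()
        sdt = fit_conditional_metad(g, (-1.0, 1.0), y)
        assert sdt.meta_d == pytest.approx(2.0, abs=1e-6)
        assert sdt.loss < 1e-10

    @pytest.mark.parametrize("y", [-0.5, 0.4, 2.0])
    def test_equal_correlations_closed_form(self, y):
        g = make_group(rhos=(0.5, 0.5, 0.0))
        sdt = fit_conditional_metad(g, (-1.0, 1.0), y)
        assert sdt.meta_d == pytest.approx(2.0 / np.sqrt(0.75), abs=1e-4)

    def test_x_reflection_negates_meta_d(self):
        g = make_group(rhos=(0.3, -0.2, 0.0))
        g_ref = make_group(mu_xc=-1.0, mu_xi=1.0, rhos=(-0.3, 0.2, 0.0))
        sdt = fit_conditional_metad(g, (-0.8, 1.1), 0.9)
        sdt_ref = fit_conditional_metad(g_ref, (-1.1, 0.8), 0.9)
        assert sdt_ref.meta_d == pytest.approx(-sdt.meta_d, abs=1e-5)

    def test_matches_grid_search_oracle(self):
        """Dense brute-force search over (meta_d, t1, t2) agrees with the
        local optimizer on randomized conditional problems."""
        from oracles import grid_search_metad

        from grtmeta.svm import _target_probs

        rng = np.random.default_rng(21)
        for _ in range(3):
            g = make_group(
                mu_xc=rng.uniform(0.3, 1.5),
                mu_xi=rng.uniform(-1.5, -0.3),
                mu_yc=rng.uniform(0.5, 1.5),
                mu_yi=rng.uniform(0.5, 1.5),
                rhos=(rng.uniform(-0.7, 0.7), rng.uniform(-0.7, 0.7), 0.0),
            )
            crit = (-1.0, 1.0)
            y = rng.uniform(-1.5, 2.5)
            sdt = fit_conditional_metad(g, crit, y)
            best_d, best_loss, _ = grid_search_metad(_target_probs(g, crit, y))
            assert abs(sdt.meta_d) == pytest.approx(best_d, abs=0.02)
            assert sdt.loss <= best_loss + 1e-6


class TestBuildCurve:
    def test_equal_rho_curve_constant(self):
        g = make_group(rhos=(0.4, 0.4, 0.0))
        curve = build_svm_curve(make_fitted(g), n_points=41)
        assert np.ptp(curve.meta_d) < 1e-6

    def test_headline_model_increasing(self):
        g = make_group(rhos=(0.5, -0.5, 0.0))
        curve = build_svm_curve(make_fitted(g), n_points=81)
        assert np.all(np.diff(curve.meta_d) > 0)
        assert curve.L_star == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_model_rejected(self):
        g = make_group(mu_yc=0.0, mu_yi=0.0)
        with pytest.raises(ValueError, match="objective criterion"):
            build_svm_curve(make_fitted(g))

    def test_participant_positions_on_likelihood_axis(self):
        g = make_group()
        fitted = make_fitted(g, n_participants=2)
        curve = build_svm_curve(fitted, n_points=21)
        expected = [
            relative_likelihood(g, p.c_y * np.sqrt(p.kappa * (1 - p.lam)))
            for p in fitted.participants
        ]
        np.testing.assert_allclose(curve.participant_positions, expected, rtol=1e-10)
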