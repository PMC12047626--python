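"""Core decision-space geometry: covariances, rectangle probabilities,
cell probabilities and the multinomial log-likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from grtmeta import (
    CountTable,
    GroupModel,
    ParticipantParams,
    StimulusCondition,
    cell_probabilities,
    log_likelihood,
    participant_covariance,
    rectangle_probability,
)

COND = list(StimulusCondition)


def random_valid_setup(rng):
    """A random valid (group, participant) pair for property tests."""
    means = np.zeros((3, 2))
    means[0] = [abs(rng.normal(1, 1)), rng.normal(1, 1)]
    means[1] = [-abs(rng.normal(1, 1)), rng.normal(1, 1)]
    group = GroupModel(means=means, correlations=rng.uniform(-0.9, 0.9, 3))
    cx = np.sort(rng.uniform(-2, 2, 2))
    part = ParticipantParams(
        "r",
        kappa=float(np.exp(rng.uniform(np.log(0.5), np.log(8)))),
        lam=float(rng.uniform(0.2, 0.8)),
        c_y=float(rng.uniform(-2, 2)),
        c_x1=float(cx[0]),
        c_x2=float(cx[1] + 1e-3),
    )
    return group, part


class TestParticipantCovariance:
    @pytest.mark.parametrize(
        "rho,kappa,lam,expected",
        [
            (0.0, 2.0, 0.5, np.eye(2)),
            (0.5, 2.0, 0.5, np.array([[1.0, 0.5], [0.5, 1.0]])),
            (0.0, 1.0, 0.5, np.diag([2.0, 2.0])),
        ],
    )
    def test_known_values(self, rho, kappa, lam, expected):
        np.testing.assert_allclose(
            participant_covariance(rho, kappa, lam), expected, atol=1e-12
        )

    @pytest.mark.parametrize(
        "rho,kappa,lam,match",
        [(0.0, -1.0, 0.5, "kappa"), (0.0, 2.0, 1.5, "lam"), (1.5, 2.0, 0.5, "rho")],
    )
    def test_domain_errors_name_offender(self, rho, kappa, lam, match):
        with pytest.raises(ValueError, match=match):
            participant_covariance(rho, kappa, lam)

    def test_always_spd(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            cov = participant_covariance(
                rng.uniform(-0.99, 0.99),
                np.exp(rng.uniform(-2, 3)),
                rng.uniform(0.01, 0.99),
            )
            assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestRectangleProbability:
    def test_orthant_independent(self):
        p = rectangle_probability([0, 0], np.eye(2), 0, np.inf, 0, np.inf)
        assert p == pytest.approx(0.25, abs=1e-12)

    def test_orthant_correlated_closed_form(self):
        # quadrant probability 1/4 + arcsin(rho)/(2 pi)
        for rho in (-0.7, 0.3, 0.5, 0.9):
            p = rectangle_probability(
                [0, 0], [[1, rho], [rho, 1]], 0, np.inf, 0, np.inf
            )
            assert p == pytest.approx(0.25 + np.arcsin(rho) / (2 * np.pi), abs=1e-9)

    def test_full_plane_is_one(self):
        p = rectangle_probability(
            [2, -1], [[2, 0.5], [0.5, 1]], -np.inf, np.inf, -np.inf, np.inf
        )
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            rectangle_probability([0, 0], np.eye(2), 1, 0, 0, 1)

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            rectangle_probability([0, 0], [[1, 2], [2, 1]], 0, 1, 0, 1)

    def test_monte_carlo_agreement(self):
        """Randomized rectangles agree with simulation within 3 SEs."""
        rng = np.random.default_rng(11)
        n = 10**6
        for _ in range(10):
            rho = rng.uniform(-0.9, 0.9)
            mean = rng.normal(0, 1, 2)
            sd = rng.uniform(0.5, 2, 2)
            cov = np.array(
                [
                    [sd[0] ** 2, rho * sd[0] * sd[1]],
                    [rho * sd[0] * sd[1], sd[1] ** 2],
                ]
            )
            a = np.sort(rng.normal(0, 2, 2))
            b = np.sort(rng.normal(0, 2, 2))
            p = rectangle_probability(mean, cov, a[0], a[1], b[0], b[1])
            z = rng.multivariate_normal(mean, cov, size=n)
            hits = (
                (z[:, 0] > a[0]) & (z[:, 0] <= a[1])
                & (z[:, 1] > b[0]) & (z[:, 1] <= b[1])
            )
            phat = hits.mean()
            se = max(np.sqrt(phat * (1 - phat) / n), 1e-6)
            assert abs(p - phat) < 3 * se


class TestCellProbabilities:
    def test_catch_quadrant_value(self, independence_group, neutral_participant):
        # P(PRESENT & CONF_CORRECT | catch) with c_y=0, c_x2=1, unit noise
        probs = cell_probabilities(
            independence_group, neutral_participant, StimulusCondition.CATCH
        )
        assert probs[5] == pytest.approx(0.5 * (1 - norm.cdf(1)), abs=1e-9)

    def test_correct_name_cell_value(self, independence_group):
        part = ParticipantParams("a", 2.0, 0.5, c_y=0.5, c_x1=-1.0, c_x2=1.0)
        probs = cell_probabilities(
            independence_group, part, StimulusCondition.CORRECT_NAME
        )
        expected = (1 - norm.cdf(-0.5)) * (1 - norm.cdf(0.0))
        assert probs[5] == pytest.approx(expected, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_probabilities_partition_unity(self, seed):
        rng = np.random.default_rng(seed)
        group, part = random_valid_setup(rng)
        for stim in COND:
            probs = cell_probabilities(group, part, stim)
            assert np.all(probs >= 0)
            assert probs.sum() == pytest.approx(1.0, abs=1e-8)

    def test_independence_factorizes(self):
        """With rho=0 every cell is a product of univariate interval
        probabilities."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            group, part = random_valid_setup(rng)
            group = GroupModel(means=group.means, correlations=np.zeros(3))
            for stim in COND:
                mu = group.mean(stim)
                sx, sy = part.sd_x, part.sd_y
                px = np.diff(
                    norm.cdf([-np.inf, part.c_x1, part.c_x2, np.inf], mu[0], sx)
                )
                py = np.diff(norm.cdf([-np.inf, part.c_y, np.inf], mu[1], sy))
                expected = np.concatenate([py[0] * px, py[1] * px])
                np.testing.assert_allclose(
                    cell_probabilities(group, part, stim), expected, atol=1e-9
                )


class TestLogLikelihood:
    def _table(self, rng, pid="a"):
        counts = rng.integers(1, 30, size=(3, 6))
        return CountTable(pid, counts)

    def test_matches_direct_summation(self, independence_group, neutral_participant):
        rng = np.random.default_rng(0)
        table = self._table(rng, "n1")
        expected = 0.0
        for stim in COND:
            p = cell_probabilities(independence_group, neutral_participant, stim)
            expected += float(table.counts[int(stim)] @ np.log(p))
        got = log_likelihood(independence_group, [neutral_participant], [table])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linear_in_counts(self, independence_group, neutral_participant):
        rng = np.random.default_rng(1)
        table = self._table(rng, "n1")
        doubled = CountTable("n1", 2 * table.counts)
        ll1 = log_likelihood(independence_group, [neutral_participant], [table])
        ll2 = log_likelihood(independence_group, [neutral_participant], [doubled])
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_invariant_to_participant_order(self, independence_group):
        rng = np.random.default_rng(2)
        parts = [
            ParticipantParams(f"p{i}", 2.0, 0.5, 0.1 * i, -1.0, 1.0)
            for i in range(3)
        ]
        tables = [self._table(rng, f"p{i}") for i in range(3)]
        ll = log_likelihood(independence_group, parts, tables)
        ll_rev = log_likelihood(independence_group, parts[::-1], tables[::-1])
        assert ll == pytest.approx(ll_rev, rel=1e-14)

    def test_mismatched_participants_rejected(self, independence_group):
        rng = np.random.default_rng(3)
        part = ParticipantParams("a", 2.0, 0.5, 0.0, -1.0, 1.0)
        with pytest.raises(ValueError, match="no parameters"):
            log_likelihood(independence_group, [part], [self._table(rng, "b")])
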