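"""Parameter transforms, identifiability anchors and the MLE driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grtmeta import (
    CountTable,
    FittedModel,
    GroupModel,
    ParticipantParams,
    StimulusCondition,
    cell_probabilities,
    fit_grt_wind,
    log_likelihood,
    pack_parameters,
    random_start,
    unpack_parameters,
    variance_accounted,
)
from grtmeta.fitting import anchor_model, apply_axis_scale, apply_scale
from grtmeta.synth import truth_to_model


class TestPackUnpack:
    def test_round_trip(self, independence_group):
        parts = [
            ParticipantParams("a", 1.7, 0.4, 0.3, -0.8, 1.1),
            ParticipantParams("b", 3.2, 0.6, -0.2, -1.5, 0.2),
        ]
        theta = pack_parameters(independence_group, parts)
        group2, parts2 = unpack_parameters(theta, 2, participant_ids=["a", "b"])
        np.testing.assert_allclose(group2.means, independence_group.means, atol=1e-12)
        np.testing.assert_allclose(
            group2.correlations, independence_group.correlations, atol=1e-12
        )
        for p, q in zip(parts, parts2):
            for attr in ("kappa", "lam", "c_y", "c_x1", "c_x2"):
                assert getattr(q, attr) == pytest.approx(getattr(p, attr), abs=1e-12)

    def test_zero_vector_neutral_values(self):
        group, (part,) = unpack_parameters(np.zeros(12), 1)
        np.testing.assert_allclose(group.correlations, 0.0)
        assert part.kappa == pytest.approx(1.0)
        assert part.lam == pytest.approx(0.5)
        assert part.c_x2 - part.c_x1 == pytest.approx(1.0)

    @given(st.lists(st.floats(-5, 5), min_size=12, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_criteria_always_ordered(self, vec):
        _, (part,) = unpack_parameters(np.array(vec), 1)
        assert part.c_x1 < part.c_x2

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            unpack_parameters(np.zeros(10), 1)


class TestRandomStart:
    def test_deterministic(self):
        np.testing.assert_array_equal(random_start(5, 3), random_start(5, 3))

    def test_seeds_differ(self):
        assert not np.array_equal(random_start(1, 3), random_start(2, 3))

    def test_unpacks_to_valid_parameters(self):
        for seed in range(300):
            theta = random_start(seed, 2)
            group, parts = unpack_parameters(theta, 2)
            # type invariants enforced in constructors; also axis convention
            assert group.mean(StimulusCondition.CORRECT_NAME)[0] >= 0
            assert group.mean(StimulusCondition.INCORRECT_NAME)[0] <= 0
            for p in parts:
                assert 0.5 * 0.999 <= p.kappa <= 8 / 0.999
                assert 0.2 <= p.lam <= 0.8


class TestScaleAnchor:
    def _setup(self):
        rng = np.random.default_rng(8)
        group = GroupModel(
            means=np.array([[1.2, 0.9], [-0.8, 1.1], [0, 0]]),
            correlations=np.array([0.4, -0.3, 0.1]),
        )
        parts = [
            ParticipantParams(f"p{i}", float(np.exp(rng.normal(0.7, 0.3))),
                              float(rng.uniform(0.3, 0.7)), 0.4, -1.0, 1.0)
            for i in range(4)
        ]
        return group, parts

    @pytest.mark.parametrize("ax,ay", [(2.0, 2.0), (0.5, 1.7), (3.1, 0.4)])
    def test_axis_scaling_preserves_cell_probabilities(self, ax, ay):
        group, parts = self._setup()
        group2, parts2 = apply_axis_scale(group, parts, ax, ay)
        for p, q in zip(parts, parts2):
            for stim in StimulusCondition:
                np.testing.assert_allclose(
                    cell_probabilities(group, p, stim),
                    cell_probabilities(group2, q, stim),
                    atol=1e-10,
                )

    def test_anchor_is_idempotent_and_pins_scale(self):
        group, parts = self._setup()
        g1, p1 = anchor_model(group, parts)
        px = np.exp(np.mean([np.log(p.kappa * p.lam) for p in p1]))
        py = np.exp(np.mean([np.log(p.kappa * (1 - p.lam)) for p in p1]))
        assert px == pytest.approx(1.0, abs=1e-10)
        assert py == pytest.approx(1.0, abs=1e-10)
        g2, p2 = anchor_model(g1, p1)
        np.testing.assert_allclose(g2.means, g1.means, atol=1e-12)

    def test_anchor_selects_unique_representative(self):
        """Two models on the same scale orbit anchor to the same point."""
        group, parts = self._setup()
        stretched = apply_axis_scale(group, parts, 1.9, 0.6)
        a1 = anchor_model(group, parts)
        a2 = anchor_model(*stretched)
        np.testing.assert_allclose(a1[0].means, a2[0].means, atol=1e-10)
        for p, q in zip(a1[1], a2[1]):
            assert p.kappa == pytest.approx(q.kappa, abs=1e-10)

    def test_uniform_scale_is_special_case(self):
        group, parts = self._setup()
        g1, _ = apply_scale(group, parts, 2.0)
        g2, _ = apply_axis_scale(group, parts, 2.0, 2.0)
        np.testing.assert_allclose(g1.means, g2.means)


class TestFitDriver:
    def test_mle_dominates_truth_on_its_own_sample(self, small_study, small_tables, small_fit):
        _, truth, _ = small_study
        true_group, true_parts = truth_to_model(truth)
        order = {t.participant_id for t in small_tables}
        true_parts = [p for p in true_parts if p.participant_id in order]
        ll_true = log_likelihood(true_group, true_parts, small_tables)
        assert small_fit.loglik >= ll_true

    def test_deterministic_given_seed(self, small_tables):
        a = fit_grt_wind(small_tables, n_restarts=1, seed=123,
                         compute_pct_variance=False)
        b = fit_grt_wind(small_tables, n_restarts=1, seed=123,
                         compute_pct_variance=False)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.group.means, b.group.means)

    def test_more_restarts_never_worse(self, small_tables):
        """Child seeds are a prefix stream, so best-of-5 is a subset of
        best-of-10 restarts."""
        few = fit_grt_wind(small_tables, n_restarts=2, seed=77,
                           compute_pct_variance=False)
        many = fit_grt_wind(small_tables, n_restarts=5, seed=77,
                            compute_pct_variance=False)
        assert many.loglik >= few.loglik - 1e-6
        assert few.restart_logliks == many.restart_logliks[: len(few.restart_logliks)]

    def test_loglik_is_best_restart(self, small_fit):
        assert small_fit.loglik == pytest.approx(
            max(small_fit.restart_logliks), abs=1e-9
        )

    def test_fitted_parameters_in_domain(self, small_fit):
        for p in small_fit.participants:
            assert p.kappa > 0
            assert 0 < p.lam < 1
            assert p.c_x1 < p.c_x2
        assert np.all(np.abs(small_fit.group.correlations) < 1)
        np.testing.assert_allclose(small_fit.group.means[2], 0.0)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="no count tables"):
            fit_grt_wind([])


class TestVarianceAccounted:
    def test_perfect_prediction_scores_100(self, small_fit):
        """Tables drawn exactly at the model's expected proportions give
        a perfect correlation."""
        from grtmeta.fitting import predicted_probabilities

        dummy = [
            CountTable(p.participant_id, np.ones((3, 6), int))
            for p in small_fit.participants
        ]
        probs = predicted_probabilities(small_fit, dummy)
        n = 100_000
        tables = [
            CountTable(
                p.participant_id,
                np.maximum((probs[i] * n).round().astype(int), 0) + 1,
            )
            for i, p in enumerate(small_fit.participants)
        ]
        assert variance_accounted(small_fit, tables) > 99.9

    def test_good_fit_on_simulated_data(self, small_fit):
        assert small_fit.pct_variance > 95.0


class TestSerialization:
    def test_json_round_trip(self, small_fit, tmp_path):
        path = tmp_path / "model.json"
        small_fit.to_json(path)
        back = FittedModel.from_json(path)
        np.testing.assert_allclose(back.group.means, small_fit.group.means)
        np.testing.assert_allclose(
            back.group.correlations, small_fit.group.correlations
        )
        assert back.loglik == small_fit.loglik
        assert back.judgment == small_fit.judgment
        for p, q in zip(back.participants, small_fit.participants):
            assert p == q
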