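"""Tests of the logistic seek model: probability, likelihood, per-subject ML
fitting, predictor encoding, inclusion filtering and group curves."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infoseek.cohort import encode_confidence_level
from infoseek.errors import InvalidArgumentError, SchemaError
from infoseek.seek_model import (
    PosteriorSummary,
    encode_predictors,
    filter_inclusion,
    fit_subject_mle,
    predict_group_curves,
    seek_probability,
    subject_nll,
    summarize_embedding,
)


def brute_force_logistic(b, conf, cost):
    """Independent straight-line oracle for the seek probability."""
    return 1.0 / (1.0 + math.exp(-(b[0] + b[1] * conf + b[2] * cost)))


def make_design(betas, n, seed, subject_id="s1"):
    rng = np.random.default_rng(seed)
    conf = encode_confidence_level(rng.integers(1, 4, size=n))
    cost = rng.integers(0, 2, size=n).astype(float)
    p = seek_probability(np.asarray(betas), conf, cost)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "sought": (rng.random(n) < p).astype(int),
            "confidence_encoded": conf,
            "cost_encoded": cost,
        }
    )


class TestSeekProbability:
    def test_symmetric_logistic_is_half(self):
        assert seek_probability([0, 0, 0], 1.7, 1.0) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        # b0=1, b1=-2, conf=0.5, b2=0 -> logistic(0) = 0.5
        assert seek_probability([1.0, -2.0, 0.0], 0.5, 0.0) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            b = rng.normal(0, 2, size=3)
            conf, cost = rng.normal(0, 1.5), float(rng.integers(0, 2))
            assert seek_probability(b, conf, cost) == pytest.approx(
                brute_force_logistic(b, conf, cost), abs=1e-12
            )

    @given(st.floats(-30, 30), st.floats(-30, 0), st.floats(-30, 0),
           st.floats(-3, 3), st.integers(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, b0, b1, b2, conf, cost):
        p = seek_probability([b0, b1, b2], conf, cost)
        assert 0 < p < 1
        # with negative slopes, higher confidence and higher cost never
        # increase the seek probability
        assert seek_probability([b0, b1, b2], conf + 0.5, cost) <= p
        assert seek_probability([b0, b1, b2], conf, 1) <= seek_probability([b0, b1, b2], conf, 0)


class TestEncodePredictors:
    @staticmethod
    def _trials(levels, costs):
        return pd.DataFrame(
            {
                "subject_id": "s1",
                "initial_conf_level": levels,
                "cost_points": costs,
                "sought": [0] * len(levels),
            }
        )

    def test_balanced_levels_get_closed_form_zscores(self):
        t = self._trials([1, 2, 3] * 10, [5, 20, 5] * 10)
        enc = encode_predictors(t)
        by_level = enc.groupby(t["initial_conf_level"])["confidence_encoded"].first()
        np.testing.assert_allclose(by_level, [-1.224745, 0.0, 1.224745], atol=1e-5)

    def test_cost_indicator(self):
        enc = encode_predictors(self._trials([1, 2, 3, 1], [5, 20, 5, 20]))
        np.testing.assert_array_equal(enc["cost_encoded"], [0, 1, 0, 1])

    def test_degenerate_confidence_encoded_as_zero(self, caplog):
        with caplog.at_level("WARNING", logger="infoseek.seek_model"):
            enc = encode_predictors(self._trials([2] * 6, [5, 20] * 3))
        assert (enc["confidence_encoded"] == 0).all()
        assert any("zero variance" in r.message for r in caplog.records)

    def test_unknown_cost_names_the_row(self):
        with pytest.raises(SchemaError, match="row 2"):
            encode_predictors(self._trials([1, 2, 3], [5, 20, 7]))

    def test_row_order_preserved(self):
        t = self._trials([3, 1, 2, 3], [20, 5, 20, 5])
        enc = encode_predictors(t)
        assert list(enc.index) == list(t.index)


class TestSubjectNLL:
    def test_single_row_at_half_is_ln2(self):
        d = pd.DataFrame({"sought": [1], "confidence_encoded": [0.0], "cost_encoded": [0.0]})
        assert subject_nll([0, 0, 0], d) == pytest.approx(math.log(2), abs=1e-12)

    def test_saturated_intercept_drives_nll_to_zero(self):
        d = pd.DataFrame({"sought": [1] * 20, "confidence_encoded": [0.0] * 20,
                          "cost_encoded": [0.0] * 20})
        assert subject_nll([400.0, 0, 0], d) == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_sum(self):
        d = make_design([0.5, -1.0, -0.5], 50, seed=3)
        b = np.array([0.3, -0.7, -0.2])
        expected = -sum(
            math.log(p if y else 1 - p)
            for y, p in zip(
                d["sought"],
                [brute_force_logistic(b, c, k) for c, k in
                 zip(d["confidence_encoded"], d["cost_encoded"])],
            )
        )
        assert subject_nll(b, d) == pytest.approx(expected, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            subject_nll([0, 0, 0], pd.DataFrame(
                {"sought": [], "confidence_encoded": [], "cost_encoded": []}))


class TestSubjectMLE:
    def test_recovery_at_large_n(self):
        truth = np.array([0.5, -1.0, -0.5])
        d = make_design(truth, 10_000, seed=21)
        fit = fit_subject_mle(d)
        assert fit.fit_flag == "ok"
        np.testing.assert_allclose(fit.vector, truth, atol=0.1)

    def test_fit_no_worse_than_truth(self):
        truth = np.array([0.2, -0.8, -0.4])
        for seed in range(5):
            d = make_design(truth, 200, seed=seed)
            fit = fit_subject_mle(d)
            if fit.fit_flag == "ok":
                assert subject_nll(fit.vector, d) <= subject_nll(truth, d) + 1e-6

    def test_separable_data_flagged(self):
        conf = np.array([-1.2, -1.2, 0.0, 0.0, 1.2, 1.2] * 4)
        d = pd.DataFrame(
            {
                "subject_id": "s1",
                "sought": (conf < 0).astype(int),
                "confidence_encoded": conf,
                "cost_encoded": 0.0,
            }
        )
        assert fit_subject_mle(d).fit_flag == "separable"

    def test_constant_outcomes_flagged_boundary(self):
        d = pd.DataFrame({"subject_id": "s1", "sought": [1] * 20,
                          "confidence_encoded": np.linspace(-1, 1, 20),
                          "cost_encoded": [0.0, 1.0] * 10})
        fit = fit_subject_mle(d)
        assert fit.fit_flag == "boundary" and fit.b0 == 10.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_subject_mle(make_design([0, 0, 0], 5, seed=0))


class TestInclusionFilter:
    @pytest.mark.parametrize(
        "rate,included",
        [(0.04, False), (0.05, True), (0.50, True), (0.95, True), (0.96, False)],
    )
    def test_bounds_inclusive(self, rate, included):
        assert filter_inclusion([rate])[0] == included

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            filter_inclusion([1.2])


def _fake_posterior(intervals):
    rows = []
    for k, (lo, hi) in enumerate(intervals):
        rows.append({"parameter": f"rho_{k}", "mean": (lo + hi) / 2,
                     "sd": (hi - lo) / 4, "q2.5": lo, "q97.5": hi,
                     "rhat": 1.0, "ess_bulk": 1000.0})
    return PosteriorSummary(table=pd.DataFrame(rows), draws={}, subject_ids=[],
                            n_chains=4, n_draws=1000)


class TestSummarizeEmbedding:
    def test_interval_excluding_zero_is_flagged(self):
        out = summarize_embedding(_fake_posterior([(-0.40, -0.07), (-0.06, 0.07), (0.0, 0.27)]))
        assert out["rho_0"]["excludes_zero"] is True
        assert out["rho_1"]["excludes_zero"] is False
        # closed-interval rule: an endpoint exactly at zero does not exclude it
        assert out["rho_2"]["excludes_zero"] is False


class TestGroupCurves:
    def test_identical_betas_give_coinciding_curves(self):
        betas = np.tile([0.0, -1.0, -0.5], (40, 1))
        dog = np.linspace(-2, 2, 40)
        out = predict_group_curves(betas, dog)
        top = out[out.group == "top_decile"].set_index("confidence_level")
        rest = out[out.group == "remainder"].set_index("confidence_level")
        np.testing.assert_allclose(top["predicted_median"], rest["predicted_median"], atol=1e-12)

    def test_predicted_curve_matches_direct_averaging(self):
        rng = np.random.default_rng(9)
        betas = rng.normal([-0.5, -1.0, -0.8], 0.5, size=(60, 3))
        dog = rng.standard_normal(60)
        out = predict_group_curves(betas, dog)
        cut = np.quantile(dog, 0.9)
        for _, row in out.iterrows():
            mask = dog >= cut if row["group"] == "top_decile" else dog < cut
            enc = encode_confidence_level(row["confidence_level"])
            ps = [0.5 * (brute_force_logistic(b, enc, 0) + brute_force_logistic(b, enc, 1))
                  for b in betas[mask]]
            assert row["predicted_median"] == pytest.approx(np.median(ps), abs=1e-12)

    def test_dogmatism_gap_largest_at_low_confidence(self):
        # population with a negative intercept shift and positive confidence
        # shift for dogmatic subjects: the groups should differ most when
        # confidence is lowest
        rng = np.random.default_rng(10)
        dog = rng.standard_normal(400)
        betas = np.column_stack([
            -0.5 - 0.8 * dog + 0.3 * rng.standard_normal(400),
            -1.0 + 0.5 * dog + 0.2 * rng.standard_normal(400),
            np.full(400, -0.8),
        ])
        out = predict_group_curves(betas, dog)
        gaps = {}
        for level in (1, 2, 3):
            sub = out[out.confidence_level == level].set_index("group")
            gaps[level] = (sub.loc["remainder", "predicted_median"]
                           - sub.loc["top_decile", "predicted_median"])
        assert gaps[1] > gaps[2] > gaps[3]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvalidArgumentError):
            predict_group_curves(np.zeros((5, 3)), np.arange(5))
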