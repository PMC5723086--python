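"""Efficiency, variance inflation, balance and bias-reduction diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from longipw import (balance_table, bias_reduction_summary,
                     diagnostics_report, estimator_variance_ratio,
                     kish_efficiency, truth_recovery, variance_inflation)

weights_arrays = arrays(float, st.integers(2, 100),
                        elements=st.floats(0.01, 50.0, allow_nan=False))


class TestKishAndInflation:
    def test_uniform_weights_are_fully_efficient(self):
        assert kish_efficiency(np.ones(10)) == 100.0
        assert variance_inflation(np.ones(10)) == 1.0

    def test_two_point_hand_computation(self):
        w = np.array([0.5, 1.5])
        assert kish_efficiency(w) == pytest.approx(80.0)      # 4 / (2*2.5)
        assert variance_inflation(w) == pytest.approx(1.25)   # 1 + 0.25

    @given(weights_arrays)
    def test_reciprocal_identity(self, w):
        assert kish_efficiency(w) * variance_inflation(w) == pytest.approx(
            100.0, abs=1e-9)

    def test_efficiency_41_67_corresponds_to_inflation_2_4(self):
        """A weight vector with variance inflation 2.4 must report a Kish
        efficiency of 41.67% — the two headline diagnostics are one number."""
        from scipy.optimize import brentq

        def gap(x):
            return variance_inflation(np.r_[np.ones(9), x]) - 2.4

        x = brentq(gap, 1.0, 50.0)
        w = np.r_[np.ones(9), x]
        assert variance_inflation(w) == pytest.approx(2.4, abs=1e-10)
        assert kish_efficiency(w) == pytest.approx(41.6667, abs=1e-3)

    def test_mean_preserving_spread_lowers_efficiency(self, rng):
        w = rng.lognormal(0, 0.3, 500)
        w = w / w.mean()
        spread = w + rng.normal(0, 0.1, 500)
        spread = np.abs(spread) + 1e-6
        spread = spread / spread.mean()
        if spread.var() > w.var():
            assert kish_efficiency(spread) < kish_efficiency(w)

    def test_scale_invariance(self, rng):
        w = rng.lognormal(0, 0.5, 100)
        assert kish_efficiency(3 * w) == pytest.approx(kish_efficiency(w))


class TestEstimatorVarianceRatio:
    def test_uniform_weights_give_unit_ratio(self, rng):
        x = rng.normal(size=200)
        assert estimator_variance_ratio(x, np.ones(200)) == pytest.approx(
            1.0, rel=0.02)

    def test_independent_weights_inflate_by_kish_factor(self, rng):
        """With weights independent of the variable, the ratio approaches
        the global variance-inflation factor."""
        n = 10_000
        x = rng.normal(size=n)
        w = rng.lognormal(0, 0.5, n)
        w = w / w.mean()
        ratio = estimator_variance_ratio(x, w)
        assert ratio == pytest.approx(variance_inflation(w), rel=0.10)

    def test_zero_variance_flagged_as_nan(self):
        assert np.isnan(estimator_variance_ratio(np.ones(50),
                                                 np.ones(50) * 2))

    def test_bootstrap_agrees_with_linearization(self, rng):
        n = 2000
        x = rng.normal(size=n)
        w = rng.lognormal(0, 0.4, n)
        lin = estimator_variance_ratio(x, w)
        boot = estimator_variance_ratio(x, w, method="bootstrap",
                                        n_boot=800, seed=5)
        assert boot == pytest.approx(lin, rel=0.2)


def _cohort_frame(rng, n=400):
    resp = (rng.random(n) < 0.6).astype(int)
    return pd.DataFrame({
        "subject_id": np.arange(n),
        "baseline_weight": rng.lognormal(0, 0.2, n),
        "response": resp,
        "group": pd.Categorical(rng.choice(["low", "mid", "high"], n),
                                categories=["low", "mid", "high"]),
        "score": rng.normal(10, 2, n),
        "band": pd.Categorical(rng.choice(["young", "old"], n),
                               categories=["young", "old"]),
    })


class TestBalanceTable:
    def test_unit_weights_make_respondent_columns_identical(self, rng):
        t = _cohort_frame(rng)
        n_resp = int(t["response"].sum())
        bal = balance_table(t.assign(baseline_weight=1.0), np.ones(n_resp),
                            ["group", "score"])
        np.testing.assert_allclose(bal["respondents_baseline_w"],
                                   bal["respondents_longitudinal_w"])

    def test_categorical_shares_sum_to_hundred(self, rng):
        t = _cohort_frame(rng)
        n_resp = int(t["response"].sum())
        w = rng.lognormal(0, 0.3, n_resp)
        bal = balance_table(t, w, ["group"])
        for col in ["whole_sample", "nonrespondents",
                    "respondents_baseline_w", "respondents_longitudinal_w"]:
            assert bal[col].sum() == pytest.approx(100.0)

    def test_strata_rows_present_and_empty_stratum_flagged(self, rng):
        t = _cohort_frame(rng)
        t["band"] = t["band"].cat.add_categories("ancient")
        n_resp = int(t["response"].sum())
        bal = balance_table(t, np.ones(n_resp), ["score"], strata="band")
        assert set(bal["stratum"]) == {"all", "young", "old", "ancient"}
        ancient = bal[bal["stratum"] == "ancient"]
        assert ancient["empty_stratum"].all()
        assert not bal[bal["stratum"] == "young"]["empty_stratum"].any()

    def test_misaligned_weights_rejected(self, rng):
        t = _cohort_frame(rng)
        with pytest.raises(ValueError, match="align"):
            balance_table(t, np.ones(3), ["group"])


class TestBiasReduction:
    def _balance(self, whole, before, after):
        return pd.DataFrame({
            "stratum": ["all"], "variable": ["v"], "level": ["mean"],
            "kind": ["metric"], "whole_sample": [whole],
            "nonrespondents": [np.nan],
            "respondents_baseline_w": [before],
            "respondents_longitudinal_w": [after],
            "empty_stratum": [False],
        })

    def test_perfect_correction_scores_hundred(self):
        out = bias_reduction_summary(self._balance(10.0, 12.0, 10.0))
        assert out["pct_bias_removed"].iloc[0] == pytest.approx(100.0)

    def test_no_change_scores_zero(self):
        out = bias_reduction_summary(self._balance(10.0, 12.0, 12.0))
        assert out["pct_bias_removed"].iloc[0] == pytest.approx(0.0)

    def test_amplification_reported_negative(self):
        out = bias_reduction_summary(self._balance(10.0, 11.0, 13.0))
        assert out["pct_bias_removed"].iloc[0] < 0

    def test_zero_prior_bias_flagged_undefined(self):
        out = bias_reduction_summary(self._balance(10.0, 10.0, 10.5))
        assert out["undefined"].iloc[0]
        assert np.isnan(out["pct_bias_removed"].iloc[0])


def test_report_assembles_all_sections(rng):
    t = _cohort_frame(rng)
    n_resp = int(t["response"].sum())
    w = rng.lognormal(0, 0.3, n_resp)
    w = w / w.mean()
    report = diagnostics_report(t, w, ["group", "score"], strata="band")
    assert set(report) >= {"efficiency_pct", "variance_inflation",
                           "weight_range", "estimator_variance_ratios",
                           "balance", "bias_summary"}
    assert report["efficiency_pct"] == pytest.approx(kish_efficiency(w))
    assert "score" in report["estimator_variance_ratios"]
    assert "group" not in report["estimator_variance_ratios"]


def test_truth_recovery_identifies_improvement(rng):
    t = _cohort_frame(rng)
    resp = t["response"] == 1
    x = t.loc[resp, "score"].to_numpy()
    truth = {"score": float(x.mean()) + 1.0}
    # weights that push the weighted mean toward the inflated "truth"
    w = np.where(x > np.median(x), 2.0, 0.5)
    out = truth_recovery(t, w, truth)["score"]
    assert out["improved"] == (out["abs_error_weighted"]
                               < out["abs_error_unweighted"])
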