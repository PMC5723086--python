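"""Categorization, missing levels and indicator encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from longipw import (MISSING_LEVEL, CategorizationRule,
                     DegenerateCovariateError, add_missing_level,
                     build_design_matrix, categorize,
                     filter_by_availability, weighted_quantile)


class TestWeightedQuantile:
    @given(arrays(float, st.integers(5, 60),
                  elements=st.floats(-50, 50, allow_nan=False)))
    def test_equal_weights_reduce_to_inverted_cdf_percentile(self, values):
        qs = np.array([0.2, 0.5, 0.8])
        ours = weighted_quantile(values, qs)
        ref = np.percentile(values, 100 * qs, method="inverted_cdf")
        np.testing.assert_array_equal(ours, ref)

    def test_weighted_case_against_brute_force(self):
        values = np.arange(1.0, 101.0)
        weights = np.where(values <= 25, 2.0, 1.0)
        q20 = weighted_quantile(values, 0.2, weights)[0]
        # brute force: smallest v with cumulative weight share >= 0.2
        order = np.argsort(values)
        cum = np.cumsum(weights[order]) / weights.sum()
        expected = values[order][np.argmax(cum >= 0.2)]
        assert q20 == expected
        assert q20 < 20  # upweighting low values pulls the cut down

    def test_invalid_levels_raise(self):
        with pytest.raises(ValueError):
            weighted_quantile([1.0, 2.0], 1.2)


class TestCategorize:
    def test_practical_bmi_style_cutpoints(self):
        rule = CategorizationRule(
            "bmi", "practical", cutpoints=(18.5, 25.0, 30.0),
            labels=("underweight", "normal", "overweight", "obese"))
        values = [16.0, 18.5, 24.9, 25.0, 31.0, np.nan]
        out = categorize(np.array(values), rule)
        assert list(out) == ["underweight", "normal", "normal", "overweight",
                             "obese", MISSING_LEVEL]
        assert list(out.categories) == ["underweight", "normal", "overweight",
                                        "obese", MISSING_LEVEL]

    def test_uniform_quintiles_split_evenly(self):
        rule = CategorizationRule("v", "quintile")
        out = categorize(np.arange(1.0, 101.0), rule)
        counts = pd.Series(out).value_counts()
        assert all(counts[f"q{i}"] == 20 for i in range(1, 6))

    def test_weighted_quintile_boundary_shifts_down(self):
        rule = CategorizationRule("v", "quintile")
        values = np.arange(1.0, 101.0)
        weights = np.where(values <= 25, 2.0, 1.0)
        out = categorize(values, rule, weights)
        n_first = (pd.Series(out) == "q1").sum()
        assert n_first < 20

    def test_quintile_needs_five_distinct_values(self):
        rule = CategorizationRule("v", "quintile")
        with pytest.raises(DegenerateCovariateError):
            categorize(np.array([1.0, 1.0, 2.0, 2.0, 3.0]), rule)

    def test_roundtrip_preserves_multiset_size(self):
        rule = CategorizationRule("v", "quintile")
        values = np.r_[np.random.default_rng(0).normal(size=83), np.nan]
        out = categorize(values, rule)
        assert pd.Series(out).value_counts().sum() == len(values)


class TestMissingLevel:
    def test_counts_missing_rows_exactly(self, tiny_table):
        out = add_missing_level(tiny_table, "colour")
        assert (out["colour"] == MISSING_LEVEL).sum() == 2
        assert list(out["colour"].cat.categories)[-1] == MISSING_LEVEL

    def test_no_missing_only_extends_inventory(self, tiny_table):
        t = tiny_table.copy()
        t["colour"] = t["colour"].fillna("red")
        out = add_missing_level(t, "colour")
        assert (out["colour"] == MISSING_LEVEL).sum() == 0
        assert MISSING_LEVEL in out["colour"].cat.categories

    def test_entirely_missing_column_flagged_degenerate(self):
        t = pd.DataFrame({"c": pd.Categorical([None, None],
                                              categories=["a"])})
        out = add_missing_level(t, "c")
        assert (out["c"] == MISSING_LEVEL).all()
        # single observed level: the design step must warn and exclude
        with pytest.warns(UserWarning, match="degenerate"):
            design = build_design_matrix(out, ["c"])
        assert design.X.shape[1] == 0

    def test_unknown_covariate_raises(self, tiny_table):
        with pytest.raises(KeyError):
            add_missing_level(tiny_table, "ghost")


class TestDesignMatrix:
    def _table(self, **cols):
        return pd.DataFrame({k: pd.Categorical(v) for k, v in cols.items()})

    def test_binary_covariate_yields_one_column(self):
        t = self._table(b=["x", "y", "x", "y"])
        d = build_design_matrix(t, ["b"])
        assert d.column_names == ["b=y"]

    def test_six_level_covariate_yields_five_columns(self):
        levels = ["l1", "l2", "l3", "l4", "l5", MISSING_LEVEL]
        t = pd.DataFrame({"c": pd.Categorical(levels, categories=levels)})
        d = build_design_matrix(t, ["c"])
        assert d.X.shape[1] == 5

    def test_column_order_is_deterministic(self):
        t = pd.DataFrame({
            "a": pd.Categorical(["p", "q", "r"], categories=["p", "q", "r"]),
            "b": pd.Categorical(["u", "v", "u"], categories=["u", "v"]),
        })
        d = build_design_matrix(t, ["a", "b"])
        assert d.column_names == ["a=q", "a=r", "b=v"]

    def test_rows_one_hot_over_reference_and_columns(self, small_cohort):
        from longipw import prepare_covariates

        cfg = small_cohort.config
        prepared, kept = prepare_covariates(
            small_cohort.table, [c.name for c in cfg.covariates])
        d = build_design_matrix(prepared, kept)
        for cov in d.covariates:
            idx = d.column_indices(cov)
            sums = d.X[:, idx].sum(axis=1)
            assert np.all((sums == 0) | (sums == 1))

    def test_unknown_reference_level_raises(self):
        t = self._table(b=["x", "y"])
        with pytest.raises(ValueError, match="reference"):
            build_design_matrix(t, ["b"], references={"b": "zz"})

    def test_restrict_preserves_metadata(self):
        t = self._table(a=["p", "q"], b=["u", "v"])
        d = build_design_matrix(t, ["a", "b"])
        sub = d.restrict(["b"])
        assert sub.column_names == ["b=v"]
        assert sub.reference == {"b": "u"}


def test_availability_filter_default_requires_full_observation(tiny_table):
    kept = filter_by_availability(tiny_table, ["colour", "height"],
                                  threshold=1.0)
    assert kept == []
    kept = filter_by_availability(tiny_table, ["colour", "height"],
                                  threshold=0.8)
    assert kept == ["colour", "height"]
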