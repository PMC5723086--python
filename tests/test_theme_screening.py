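"""Screening-stage behaviour: ranking, merging, stopping, invariances."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from longipw import (CohortConfig, ConfigurationError, CovariateSpec,
                     UnfittableThemeError, bootstrap_auc_stop,
                     build_design_matrix, fit_theme_lasso, generate_cohort,
                     merge_significant, prepare_covariates, screen,
                     weighted_auc)


def _noise_design(seed, n=2000, p=5, strong_logor=None):
    """Binary covariates x1..xp; optionally x1 drives response."""
    covs = [CovariateSpec(f"x{i+1}", "t", levels=("a", "b"),
                          probs=(0.5, 0.5)) for i in range(p)]
    coefs = {"x1": {"b": strong_logor}} if strong_logor else {}
    cfg = CohortConfig(n_subjects=n, seed=seed, covariates=covs,
                       dropout_intercept=0.3, dropout_coefs=coefs)
    cohort = generate_cohort(cfg)
    prepared, kept = prepare_covariates(cohort.table,
                                        [c.name for c in covs])
    design = build_design_matrix(prepared, kept)
    y = prepared["response"].to_numpy(dtype=float)
    w = prepared["baseline_weight"].to_numpy(dtype=float)
    return design, y, w


class TestThemeLasso:
    def test_noise_theme_selects_almost_nothing(self):
        """Pure-noise themes keep at most one false positive most of the time."""
        hits = 0
        for seed in range(10):
            design, y, w = _noise_design(seed)
            fit = fit_theme_lasso(design, y, w, seed=seed, theme="noise")
            hits += len(fit.significant) <= 1
        assert hits >= 8

    def test_strong_predictor_ranked_first(self):
        wins = 0
        for seed in range(5):
            design, y, w = _noise_design(100 + seed, p=6,
                                         strong_logor=float(np.log(0.2)))
            fit = fit_theme_lasso(design, y, w, seed=seed)
            wins += fit.ranking[0] == "x1"
        assert wins >= 4

    def test_equal_weights_match_unweighted_fit(self):
        design, y, w = _noise_design(7, strong_logor=-1.0)
        a = fit_theme_lasso(design, y, np.ones_like(y), seed=0)
        b = fit_theme_lasso(design, y, np.full_like(y, 3.7), seed=0)
        assert a.ranking == b.ranking
        assert a.significant == b.significant
        np.testing.assert_allclose(a.cv.path.coefs, b.cv.path.coefs,
                                   atol=1e-10)

    def test_never_entering_covariate_ranks_last(self):
        design, y, w = _noise_design(3, p=3, strong_logor=-1.5)
        fit = fit_theme_lasso(design, y, w, seed=1)
        never = [c for c in fit.covariates if fit.exit_lambda[c] == 0.0]
        for c in never:
            assert fit.ranking.index(c) >= len(fit.ranking) - len(never)

    def test_exit_tie_breaks_by_coef_then_declaration_order(self):
        """Documented tie rule: exit point, then |coef| at the optimum,
        then declaration order."""
        from longipw import rank_by_path
        from longipw.theme_screening import ThemeFit

        fit = ThemeFit(theme="t", covariates=["a", "b", "c", "d"],
                       cv=None, design=None)
        fit.exit_lambda = {"a": 0.1, "b": 0.1, "c": 0.3, "d": 0.1}
        fit.coef_at_opt = {"a": 0.2, "b": 0.5, "c": 0.1, "d": 0.2}
        assert rank_by_path(fit) == ["c", "b", "a", "d"]

    def test_single_response_class_is_unfittable(self):
        design, y, w = _noise_design(5, n=100)
        with pytest.raises(UnfittableThemeError, match="single response"):
            fit_theme_lasso(design, np.ones_like(y), w)

    def test_too_few_rows_is_unfittable(self):
        design, y, w = _noise_design(5, n=100)
        mask = np.arange(len(y)) < 8
        with pytest.raises(UnfittableThemeError, match="20 rows"):
            fit_theme_lasso(design.subset_rows(mask), y[:8], w[:8])


class TestMergePlan:
    def _fits(self, sig_by_theme):
        class Stub:
            def __init__(self, sig):
                self.significant = sig
        return {t: Stub(s) for t, s in sig_by_theme.items()}

    def test_disjoint_sets_pool_additively(self):
        fits = self._fits({"t1": ["a", "b"], "t2": ["c"], "t3": []})
        merged = merge_significant(fits, {"t1": "A", "t2": "A", "t3": "B"})
        assert merged == {"A": ["a", "b", "c"]}

    def test_identity_merge_keeps_themes(self):
        fits = self._fits({"t1": ["a"], "t2": ["b"]})
        merged = merge_significant(fits, None)
        assert merged == {"t1": ["a"], "t2": ["b"]}

    def test_uncovered_theme_raises_naming_it(self):
        fits = self._fits({"t1": ["a"], "orphan": ["b"]})
        with pytest.raises(ConfigurationError, match="orphan"):
            merge_significant(fits, {"t1": "A"})


class TestWeightedAuc:
    def test_matches_sklearn_with_weights_and_ties(self, rng):
        y = (rng.random(300) < 0.4).astype(float)
        scores = np.round(rng.random(300), 2)  # force ties
        w = rng.lognormal(0, 0.4, 300)
        ours = weighted_auc(y, scores, w)
        ref = roc_auc_score(y, scores, sample_weight=w)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_degenerate_single_class_returns_half(self):
        assert weighted_auc(np.ones(5), np.arange(5.0)) == 0.5


class TestBootstrapStop:
    def test_growth_is_monotone_and_recorded(self):
        design, y, w = _noise_design(11, p=5, strong_logor=-1.2)
        fit = fit_theme_lasso(design, y, w, seed=0)
        selected, traj = bootstrap_auc_stop(
            {"t": fit.ranking}, design, y, w, start_k=1, n_boot=300, seed=3)
        counts = [s.n_predictors for s in traj]
        assert counts == sorted(counts)
        assert len(selected) >= 1
        assert traj[0].p_value is None
        for step in traj[1:]:
            assert step.p_value is not None

    def test_small_bootstrap_rejected(self):
        design, y, w = _noise_design(11)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_auc_stop({"t": ["x1"]}, design, y, w, n_boot=50)

    def test_empty_ranking_rejected(self):
        design, y, w = _noise_design(11)
        with pytest.raises(ConfigurationError, match="empty"):
            bootstrap_auc_stop({"t": []}, design, y, w)


class TestScreenEndToEnd:
    def test_seed_determinism(self, small_design):
        design, y, w = small_design
        theme_map = {"g1": design.covariates[:6], "g2": design.covariates[6:]}
        a = screen(design, y, w, theme_map, cv_seed=5, bootstrap_seed=6)
        b = screen(design, y, w, theme_map, cv_seed=5, bootstrap_seed=6)
        assert a.to_dict() == b.to_dict()

    def test_doubling_weights_changes_nothing(self, small_design):
        design, y, w = small_design
        theme_map = {"g1": design.covariates[:6], "g2": design.covariates[6:]}
        a = screen(design, y, w, theme_map, cv_seed=5, bootstrap_seed=6)
        b = screen(design, y, 2.0 * w, theme_map, cv_seed=5, bootstrap_seed=6)
        assert a.selected == b.selected
        assert [s.auc for s in a.trajectory] == [s.auc for s in b.trajectory]

    def test_selected_covered_by_candidates(self, small_design):
        design, y, w = small_design
        theme_map = {"g1": design.covariates[:6], "g2": design.covariates[6:]}
        result = screen(design, y, w, theme_map, cv_seed=5, bootstrap_seed=6)
        assert set(result.selected) <= set(result.candidates)
        assert result.selected_count == len(result.selected)

    def test_json_serialization_roundtrip(self, small_design, tmp_path):
        import json

        design, y, w = small_design
        theme_map = {"g1": design.covariates[:6], "g2": design.covariates[6:]}
        result = screen(design, y, w, theme_map, cv_seed=5, bootstrap_seed=6)
        path = tmp_path / "screening.json"
        result.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["selected"] == result.selected
        result.export_paths(tmp_path / "paths.csv")
        assert (tmp_path / "paths.csv").read_text().startswith("# theme:")
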