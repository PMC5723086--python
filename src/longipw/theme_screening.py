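"""Step 1 — theme-wise LASSO screening with a bootstrap-AUC stopping rule.

Candidate covariates are grouped into content-defined "context themes".
Within each theme a weighted LASSO-logistic model of wave-1 participation
is fitted over the full penalty path with 10-fold cross-validation;
covariates that keep a nonzero level coefficient at the CV-optimal penalty
count as the theme's significant predictors, and the order in which
covariates leave the path as the penalty grows (their exit points) ranks
their predictive strength.  Significant predictors are then regrouped into
merged themes, re-ranked the same way, and the final candidate count is
fixed by a forward AUC procedure: starting from the top-ranked predictors
of each merged theme, covariates are added by rank (round-robin across
themes) and the gain in the weighted AUC of an unpenalized refit is tested
with a paired subject-level bootstrap; growth stops at the first addition
whose gain is not significant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._lasso import CVLassoResult, cv_lasso_logistic, fit_weighted_logistic
from .covariate_prep import DesignMatrix
from .synthetic_cohort import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "UnfittableThemeError",
    "ThemeFit",
    "AucStep",
    "ScreeningResult",
    "fit_theme_lasso",
    "rank_by_path",
    "merge_significant",
    "weighted_auc",
    "bootstrap_auc_stop",
    "screen",
]


class UnfittableThemeError(ValueError):
    """A theme whose data cannot support a logistic fit."""


@dataclass
class ThemeFit:
    """Penalty-path fit of one theme's covariates."""

    theme: str
    covariates: list[str]
    cv: CVLassoResult = field(repr=False)
    design: DesignMatrix = field(repr=False)
    significant: list[str] = field(default_factory=list)
    exit_lambda: dict[str, float] = field(default_factory=dict)
    coef_at_opt: dict[str, float] = field(default_factory=dict)
    ranking: list[str] = field(default_factory=list)
    seed: int = 0


def fit_theme_lasso(
    design: DesignMatrix,
    response: np.ndarray,
    baseline_weights: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    *,
    theme: str = "",
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> ThemeFit:
    """Weighted LASSO path + CV for the covariates of one theme.

    A covariate is *significant* if any of its level coefficients is
    nonzero at the CV-optimal penalty; its *exit point* is the largest
    penalty at which any level coefficient is nonzero.
    """
    if design.X.shape[1] == 0:
        raise ConfigurationError(f"theme {theme or '?'} has no covariates")
    y = np.asarray(response, dtype=float)
    if len(y) < 20:
        raise UnfittableThemeError(
            f"theme {theme or '?'}: need at least 20 rows, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise UnfittableThemeError(
            f"theme {theme or '?'}: single response class")
    cv = cv_lasso_logistic(
        design.X, y, baseline_weights, n_folds=n_folds, seed=seed,
        n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
    )
    opt = cv.lambda_opt_index
    fit = ThemeFit(theme=theme, covariates=list(design.covariates), cv=cv,
                   design=design, seed=seed)
    for cov in design.covariates:
        idx = design.column_indices(cov)
        fit.exit_lambda[cov] = max(
            cv.path.entry_lambda(j) for j in idx)
        fit.coef_at_opt[cov] = float(
            np.max(np.abs(cv.path.coefs[opt, idx])))
        if fit.coef_at_opt[cov] > 0:
            fit.significant.append(cov)
    fit.ranking = rank_by_path(fit)
    return fit


def rank_by_path(fit: ThemeFit) -> list[str]:
    """Covariates by descending shrinkage-path exit point.

    A later exit (the covariate survives a stronger penalty) means a
    stronger predictor.  Exit-point ties break by larger maximum absolute
    coefficient at the CV-optimal penalty, then by declaration order.
    """
    decl = {c: i for i, c in enumerate(fit.covariates)}
    return sorted(
        fit.covariates,
        key=lambda c: (-fit.exit_lambda[c], -fit.coef_at_opt[c], decl[c]),
    )


def merge_significant(
    theme_fits: dict[str, ThemeFit],
    merge_plan: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """Pool per-theme significant sets into merged themes.

    ``merge_plan`` maps each original theme to its merged theme; ``None``
    keeps every theme separate.  Every significant covariate must be
    covered by the plan.
    """
    merged: dict[str, list[str]] = {}
    for theme, fit in theme_fits.items():
        if merge_plan is None:
            target = theme
        else:
            target = merge_plan.get(theme)
            if target is None and fit.significant:
                raise ConfigurationError(
                    f"merge plan does not cover theme {theme!r} with "
                    f"significant covariates {fit.significant}")
        for cov in fit.significant:
            merged.setdefault(target, []).append(cov)
    return {t: covs for t, covs in merged.items() if covs}


# ---------------------------------------------------------------------------
# Weighted AUC and the paired bootstrap comparison
# ---------------------------------------------------------------------------

def weighted_auc(y: np.ndarray, scores: np.ndarray,
                 weights: np.ndarray | None = None) -> float:
    """Weighted area under the ROC curve (ties counted half)."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    group, order = _tie_groups(np.asarray(scores, dtype=float))
    return _auc_from_groups(y[order], w[order], group)


def _tie_groups(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    new = np.empty(len(s), dtype=bool)
    new[0] = True
    new[1:] = s[1:] != s[:-1]
    return np.cumsum(new) - 1, order


def _auc_from_groups(y_sorted, w_sorted, group) -> float:
    G = group[-1] + 1
    P = np.bincount(group, weights=w_sorted * y_sorted, minlength=G)
    N = np.bincount(group, weights=w_sorted * (1 - y_sorted), minlength=G)
    tp, tn = P.sum(), N.sum()
    if tp <= 0 or tn <= 0:
        return 0.5
    cum_below = np.cumsum(N) - N
    return float((P * (cum_below + 0.5 * N)).sum() / (tp * tn))


def _bootstrap_delta_p(
    y: np.ndarray,
    s_small: np.ndarray,
    s_large: np.ndarray,
    w: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """One-sided paired-bootstrap p for AUC(large) - AUC(small) > 0.

    Subjects are resampled with replacement; both models' (fixed) scores
    travel with the subject, so the AUC difference is evaluated on the same
    resample.  p = fraction of draws with a non-positive difference.
    """
    n = len(y)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)

    def batch_auc(scores: np.ndarray) -> np.ndarray:
        group, order = _tie_groups(scores)
        starts = np.flatnonzero(np.r_[True, np.diff(group) > 0])
        wy = (w * y)[order]
        wn = (w * (1 - y))[order]
        C = counts[:, order]
        P = np.add.reduceat(C * wy, starts, axis=1)
        N = np.add.reduceat(C * wn, starts, axis=1)
        tp = P.sum(axis=1)
        tn = N.sum(axis=1)
        cum_below = np.cumsum(N, axis=1) - N
        num = (P * (cum_below + 0.5 * N)).sum(axis=1)
        denom = tp * tn
        out = np.full(n_boot, 0.5)
        ok = denom > 0
        out[ok] = num[ok] / denom[ok]
        return out

    delta = batch_auc(s_large) - batch_auc(s_small)
    return float(np.mean(delta <= 0))


@dataclass
class AucStep:
    n_predictors: int
    added: str | None
    auc: float
    p_value: float | None


def _fit_and_score(design: DesignMatrix, covs: list[str], y, w) -> np.ndarray:
    sub = design.restrict(covs)
    b0, beta, conv = fit_weighted_logistic(sub.X, y, w)
    if not conv or np.max(np.abs(beta), initial=0.0) > 30:
        logger.warning(
            "quasi-separation in unpenalized fit on %s; ridge fallback", covs)
        b0, beta, _ = fit_weighted_logistic(sub.X, y, w, ridge=1e-3)
    return expit(b0 + sub.X @ beta)


def bootstrap_auc_stop(
    rankings: dict[str, list[str]],
    design: DesignMatrix,
    response: np.ndarray,
    baseline_weights: np.ndarray,
    *,
    start_k: int = 3,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    growth: str = "round_robin",
    exit_scores: dict[str, float] | None = None,
) -> tuple[list[str], list[AucStep]]:
    """Grow the predictor set by rank until the AUC gain stops being real.

    The starting model holds the ``start_k`` top-ranked predictors of each
    merged theme.  Each further candidate (round-robin over themes by rank,
    or in global exit-point order with ``growth='global'``) is admitted only
    if the weighted-AUC increase of the unpenalized refit is significant in
    a one-sided paired bootstrap at level ``alpha``; the first failed
    addition stops the growth and is excluded.
    """
    if not any(rankings.values()):
        raise ConfigurationError("empty merged ranking")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    y = np.asarray(response, dtype=float)
    w = np.asarray(baseline_weights, dtype=float)
    w = w * (len(w) / w.sum())
    rng = np.random.default_rng(seed)

    themes = list(rankings)
    current: list[str] = []
    for t in themes:
        current.extend(rankings[t][:start_k])
    if growth == "global":
        scores = exit_scores or {}
        pending = sorted(
            (c for t in themes for c in rankings[t][start_k:]),
            key=lambda c: -scores.get(c, 0.0))
    elif growth == "round_robin":
        pending = []
        depth = start_k
        while True:
            layer = [rankings[t][depth] for t in themes
                     if depth < len(rankings[t])]
            if not layer:
                break
            pending.extend(layer)
            depth += 1
    else:
        raise ValueError(f"unknown growth order {growth!r}")

    scores_cur = _fit_and_score(design, current, y, w)
    auc_cur = weighted_auc(y, scores_cur, w)
    trajectory = [AucStep(len(current), None, auc_cur, None)]
    for cov in pending:
        trial = current + [cov]
        scores_new = _fit_and_score(design, trial, y, w)
        auc_new = weighted_auc(y, scores_new, w)
        p = _bootstrap_delta_p(y, scores_cur, scores_new, w, n_boot, rng)
        trajectory.append(AucStep(len(trial), cov, auc_new, p))
        if p > alpha:
            break
        current, scores_cur, auc_cur = trial, scores_new, auc_new
    return current, trajectory


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Everything step 1 produced, both LASSO rounds plus the AUC stop."""

    first_round: dict[str, ThemeFit]
    merged_map: dict[str, list[str]]
    second_round: dict[str, ThemeFit]
    candidates: list[str]
    trajectory: list[AucStep]
    selected: list[str]
    selected_count: int
    cv_seed: int
    bootstrap_seed: int

    def to_dict(self) -> dict:
        def theme_dict(f: ThemeFit) -> dict:
            return {
                "covariates": f.covariates,
                "significant": f.significant,
                "ranking": f.ranking,
                "exit_lambda": f.exit_lambda,
                "lambda_opt": f.cv.lambda_opt,
            }
        return {
            "first_round": {t: theme_dict(f)
                            for t, f in self.first_round.items()},
            "merged_map": self.merged_map,
            "second_round": {t: theme_dict(f)
                             for t, f in self.second_round.items()},
            "candidates": self.candidates,
            "trajectory": [
                {"n_predictors": s.n_predictors, "added": s.added,
                 "auc": s.auc, "p_value": s.p_value}
                for s in self.trajectory],
            "selected": self.selected,
            "selected_count": self.selected_count,
            "cv_seed": self.cv_seed,
            "bootstrap_seed": self.bootstrap_seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def export_paths(self, path, round: str = "second") -> None:
        """Shrinkage paths as delimited text (one block per theme)."""
        fits = self.second_round if round == "second" else self.first_round
        with open(path, "w") as fh:
            for theme, fit in fits.items():
                cols = fit.design.column_names
                fh.write(f"# theme: {theme}\n")
                fh.write("lambda," + ",".join(cols) + "\n")
                for lam, row in zip(fit.cv.path.lambdas, fit.cv.path.coefs):
                    fh.write(f"{lam:.8g}," +
                             ",".join(f"{v:.8g}" for v in row) + "\n")


def screen(
    design: DesignMatrix,
    response: np.ndarray,
    baseline_weights: np.ndarray,
    theme_map: dict[str, list[str]],
    merge_plan: dict[str, str] | None = None,
    *,
    n_folds: int = 10,
    start_k: int = 3,
    alpha: float = 0.05,
    n_boot: int = 1000,
    cv_seed: int = 0,
    bootstrap_seed: int = 0,
    growth: str = "round_robin",
    n_lambda: int = 100,
) -> ScreeningResult:
    """Run the whole step-1 screen and fix the candidate predictor count."""
    available = set(design.covariates)
    first: dict[str, ThemeFit] = {}
    for theme, covs in theme_map.items():
        covs = [c for c in covs if c in available]
        if not covs:
            continue
        first[theme] = fit_theme_lasso(
            design.restrict(covs), response, baseline_weights,
            n_folds=n_folds, seed=cv_seed, theme=theme, n_lambda=n_lambda)

    merged_map = merge_significant(first, merge_plan)
    candidates = [c for covs in merged_map.values() for c in covs]

    second: dict[str, ThemeFit] = {}
    rankings: dict[str, list[str]] = {}
    exit_scores: dict[str, float] = {}
    for theme, covs in merged_map.items():
        prior = first.get(theme)
        if prior is not None and prior.covariates == covs:
            # identity merge with nothing screened out: the re-ranking fit
            # would be byte-identical, so reuse it
            second[theme] = prior
        else:
            second[theme] = fit_theme_lasso(
                design.restrict(covs), response, baseline_weights,
                n_folds=n_folds, seed=cv_seed, theme=theme, n_lambda=n_lambda)
        rankings[theme] = second[theme].ranking
        exit_scores.update(second[theme].exit_lambda)

    if not candidates:
        logger.warning("no significant covariates in any theme; "
                       "selection is empty")
        return ScreeningResult(first, merged_map, second, [], [], [], 0,
                               cv_seed, bootstrap_seed)

    selected, trajectory = bootstrap_auc_stop(
        rankings, design, response, baseline_weights,
        start_k=start_k, alpha=alpha, n_boot=n_boot, seed=bootstrap_seed,
        growth=growth, exit_scores=exit_scores)
    return ScreeningResult(
        first_round=first, merged_map=merged_map, second_round=second,
        candidates=candidates, trajectory=trajectory, selected=selected,
        selected_count=len(selected), cv_seed=cv_seed,
        bootstrap_seed=bootstrap_seed)
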