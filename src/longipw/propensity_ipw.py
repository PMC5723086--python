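"""Step 2 — the final participation model and inverse-probability weights.

The screened candidates enter one more weighted LASSO-logistic model with
10-fold cross-validation; covariates with any nonzero level coefficient at
the CV-optimal penalty form the final predictive factor subset.  Reported
odds ratios, confidence intervals and p-values come from an unpenalized
weighted logistic refit on that subset ("relaxed" reporting — penalized
coefficients are shrunken and carry no Wald inference), and so do the
per-subject predicted participation probabilities (PRED).  Each wave-1
respondent's raw longitudinal weight is 1/PRED; nonrespondents receive no
longitudinal weight.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from ._lasso import cv_lasso_logistic
from .covariate_prep import DesignMatrix
from .theme_screening import weighted_auc

logger = logging.getLogger(__name__)

__all__ = [
    "LevelEffect",
    "PropensityFit",
    "fit_final_model",
    "predict_probability",
    "inverse_probability",
    "model_report",
    "format_report",
]

#: Probability clipping bound before inversion; guards the arithmetic only —
#: extreme weights are governed statistically by the later trimming step.
CLIP_EPS = 1e-6


@dataclass
class LevelEffect:
    covariate: str
    level: str
    coef: float
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    reference: bool = False


@dataclass
class PropensityFit:
    """Final participation model: selection, relaxed refit, and PRED."""

    selected: list[str]
    effects: list[LevelEffect]
    intercept: float
    pred: np.ndarray = field(repr=False)
    n: int
    auc: float
    nagelkerke_r2: float
    minus2ll: float
    lambda_opt: float
    seed: int
    design: DesignMatrix = field(repr=False, default=None)
    clipped: int = 0

    @property
    def coef_by_column(self) -> dict[str, float]:
        return {f"{e.covariate}={e.level}": e.coef
                for e in self.effects if not e.reference}


def _nagelkerke(ll1: float, ll0: float, n_eff: float) -> float:
    """Nagelkerke pseudo-R^2 from fitted and null weighted log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n_eff)
    max_cs = 1.0 - np.exp(2.0 * ll0 / n_eff)
    if max_cs <= 0:
        return 0.0
    return float(cox_snell / max_cs)


def _weighted_refit(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Unpenalized weighted logistic refit with Wald inference."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Xc, family=sm.families.Binomial(), freq_weights=w)
        res = model.fit(maxiter=200)
    return res


def fit_final_model(
    design: DesignMatrix,
    response: np.ndarray,
    baseline_weights: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    *,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    eps: float = CLIP_EPS,
) -> PropensityFit:
    """LASSO-select the final factor subset, then refit it unpenalized.

    ``design`` holds the screened candidates (all rows, respondents and
    nonrespondents).  An empty selection at the optimum falls back to an
    intercept-only model with a prominent warning, in which case PRED is
    the weighted response rate for everyone.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    w = np.asarray(baseline_weights, dtype=float)
    w = w * (n / w.sum())

    selected: list[str] = []
    lambda_opt = float("nan")
    if design.X.shape[1] > 0:
        cv = cv_lasso_logistic(
            design.X, y, w, n_folds=n_folds, seed=seed, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio)
        lambda_opt = cv.lambda_opt
        coef_opt = cv.path.coefs[cv.lambda_opt_index]
        for cov in design.covariates:
            if np.any(coef_opt[design.column_indices(cov)] != 0):
                selected.append(cov)

    if not selected:
        warnings.warn(
            "final LASSO selected no covariates; falling back to an "
            "intercept-only participation model — every respondent gets the "
            "same weight", UserWarning, stacklevel=2)
        sub = DesignMatrix(X=np.empty((n, 0)), columns=[], reference={},
                           covariates=[])
    else:
        sub = design.restrict(selected)

    res = _weighted_refit(sub.X, y, w)
    params = np.asarray(res.params)
    conf = np.asarray(res.conf_int())
    pvals = np.asarray(res.pvalues)
    intercept = float(params[0])

    effects: list[LevelEffect] = []
    for cov in sub.covariates:
        effects.append(LevelEffect(cov, sub.reference[cov], 0.0, 1.0,
                                   None, None, None, reference=True))
        for k, col in enumerate(sub.columns):
            if col.covariate != cov:
                continue
            b = float(params[k + 1])
            effects.append(LevelEffect(
                cov, col.level, b, float(np.exp(b)),
                float(np.exp(conf[k + 1, 0])), float(np.exp(conf[k + 1, 1])),
                float(pvals[k + 1])))

    eta = intercept + (sub.X @ params[1:] if sub.X.shape[1] else np.zeros(n))
    pred = expit(eta)
    clipped = int(np.sum((pred < eps) | (pred > 1 - eps)))
    if clipped:
        logger.warning("clipped %d predicted probabilities to [%g, 1-%g]",
                       clipped, eps, eps)
    pred = np.clip(pred, eps, 1 - eps)

    ll1 = float(res.llf)
    null = _weighted_refit(np.empty((n, 0)), y, w)
    ll0 = float(null.llf)
    fit = PropensityFit(
        selected=selected,
        effects=effects,
        intercept=intercept,
        pred=pred,
        n=n,
        auc=weighted_auc(y, pred, w),
        nagelkerke_r2=_nagelkerke(ll1, ll0, n_eff=float(w.sum())),
        minus2ll=-2.0 * ll1,
        lambda_opt=lambda_opt,
        seed=seed,
        design=sub,
        clipped=clipped,
    )
    return fit


def predict_probability(
    fit: PropensityFit,
    design: DesignMatrix,
    *,
    eps: float = CLIP_EPS,
    unseen: str = "reference",
) -> np.ndarray:
    """Participation probability for new rows under the fitted model.

    Rows must encode all selected covariates; a column the fit does not
    know is ignored, which maps unseen levels onto the reference (warned;
    set ``unseen='error'`` to fail instead).
    """
    coef = fit.coef_by_column
    eta = np.full(design.X.shape[0], fit.intercept, dtype=float)
    known = set()
    for j, col in enumerate(design.columns):
        if col.name in coef:
            eta += design.X[:, j] * coef[col.name]
            known.add(col.name)
    for cov in fit.selected:
        if cov not in design.covariates:
            raise ValueError(f"design is missing selected covariate {cov!r}")
    extra = [c.name for c in design.columns
             if c.covariate in fit.selected and c.name not in coef]
    if extra:
        msg = f"levels unseen at fit time mapped to reference: {extra}"
        if unseen == "error":
            raise ValueError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    prob = expit(eta)
    n_clip = int(np.sum((prob < eps) | (prob > 1 - eps)))
    if n_clip:
        logger.warning("clipped %d probabilities", n_clip)
    return np.clip(prob, eps, 1 - eps)


def inverse_probability(pred: np.ndarray) -> np.ndarray:
    """Raw inverse-probability weight 1/PRED (respondent rows only)."""
    pred = np.asarray(pred, dtype=float)
    if np.any(pred <= 0) or np.any(pred > 1):
        raise ValueError("probabilities must lie in (0, 1]")
    return 1.0 / pred


def model_report(fit: PropensityFit) -> dict:
    """Structured model report: per-level odds ratios plus model summary."""
    blocks: dict[str, list[dict]] = {}
    for e in fit.effects:
        blocks.setdefault(e.covariate, []).append({
            "level": e.level,
            "odds_ratio": e.odds_ratio,
            "ci": None if e.reference else [e.ci_low, e.ci_high],
            "p_value": e.p_value,
            "reference": e.reference,
        })
    return {
        "selected": fit.selected,
        "covariates": blocks,
        "model_info": {
            "n": fit.n,
            "nagelkerke_r2": fit.nagelkerke_r2,
            "minus2_log_likelihood": fit.minus2ll,
            "auc": fit.auc,
            "lambda_opt": fit.lambda_opt,
        },
    }


def format_report(fit: PropensityFit) -> str:
    """Text table: Variable, Value, Odds Ratio (95% CI), p-value."""
    lines = [f"{'Variable':<24}{'Value':<16}{'Odds Ratio':<22}{'p-value':<8}"]
    lines.append("-" * 70)
    for e in fit.effects:
        if e.reference:
            orx, p = "1.00", ""
        else:
            orx = f"{e.odds_ratio:.2f} ({e.ci_low:.2f}-{e.ci_high:.2f})"
            p = "<.01" if e.p_value < 0.01 else f"{e.p_value:.2f}"
        lines.append(f"{e.covariate:<24}{e.level:<16}{orx:<22}{p:<8}")
    lines.append("-" * 70)
    lines.append(
        f"N: {fit.n}; adjusted R2 = {fit.nagelkerke_r2:.2f} (Nagelkerke); "
        f"-2 log Likelihood: {fit.minus2ll:.2f}; AUC: {100 * fit.auc:.1f}%")
    return "\n".join(lines)


def save_fit(fit: PropensityFit, path) -> None:
    out = model_report(fit)
    out["intercept"] = fit.intercept
    out["coefficients"] = fit.coef_by_column
    out["pred"] = np.round(fit.pred, 12).tolist()
    out["reference_levels"] = (fit.design.reference
                               if fit.design is not None else {})
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
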