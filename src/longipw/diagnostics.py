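"""What the weights did: efficiency, variance inflation, balance.

Weighting repairs bias at a variance price.  For mean-one weights the
variance of a weighted estimator inflates by ``1 + s_w^2`` (``s_w^2`` the
variance of the weights), and the Kish weighting efficiency
``100 * (sum w)^2 / (n * sum w^2)`` is the effective-sample-size fraction
retained — the exact reciprocal of that inflation factor under the
population-variance convention used here.  Balance tables compare variable
distributions across the whole baseline sample, nonrespondents, and
respondents under baseline vs. longitudinal weights; the bias-reduction
summary scores how much of the respondent-vs-whole-sample gap the
longitudinal weights removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "kish_efficiency",
    "variance_inflation",
    "estimator_variance_ratio",
    "balance_table",
    "bias_reduction_summary",
    "diagnostics_report",
    "truth_recovery",
    "format_diagnostics",
]


def _as_weights(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise ValueError("need a 1-d weight vector of length >= 2")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w


def kish_efficiency(weights) -> float:
    """Kish effective-sample-size ratio, in percent: 100 (Σw)² / (n Σw²)."""
    w = _as_weights(weights)
    return float(100.0 * w.sum() ** 2 / (len(w) * (w @ w)))


def variance_inflation(weights) -> float:
    """1 + population variance of the mean-scaled weights.

    Equals 100 / kish_efficiency exactly (divide-by-n variance convention).
    """
    w = _as_weights(weights)
    ws = w / w.mean()
    return float(1.0 + ws.var())  # ddof=0


def estimator_variance_ratio(
    values,
    weights,
    method: str = "linearization",
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Variance of the weighted vs. unweighted mean of one variable.

    'linearization' uses the with-replacement approximation
    Σ w_i²(x_i − x̄_w)² / (Σw_i)² against s²/n; 'bootstrap' replaces both
    by resampling variances of the two means.  Returns the ratio (1 means
    no inflation); NaN when the unweighted variance is zero.
    """
    x = np.asarray(values, dtype=float)
    w = _as_weights(weights)
    if x.shape != w.shape:
        raise ValueError("values and weights must be aligned")
    n = len(x)
    s2 = x.var(ddof=1)
    if s2 == 0:
        return float("nan")
    if method == "linearization":
        xbar_w = np.average(x, weights=w)
        var_w = float((w**2 @ (x - xbar_w) ** 2) / w.sum() ** 2)
        return var_w / (s2 / n)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, wb = x[idx], w[idx]
        wmeans = (xb * wb).sum(axis=1) / wb.sum(axis=1)
        umeans = xb.mean(axis=1)
        vu = umeans.var(ddof=1)
        if vu == 0:
            return float("nan")
        return float(wmeans.var(ddof=1) / vu)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Balance tables
# ---------------------------------------------------------------------------

def _wmean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = np.average(x, weights=w)
    return float(m), float(np.sqrt(np.average((x - m) ** 2, weights=w)))


def _column_stats(sub: pd.DataFrame, weights: np.ndarray, variable: str):
    """Rows (level, kind, value, sd) for one variable in one column group."""
    col = sub[variable]
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
        cats = (col.cat.categories if isinstance(col.dtype, pd.CategoricalDtype)
                else pd.unique(col.dropna()))
        total = weights[col.notna().to_numpy()].sum()
        rows = []
        for lev in cats:
            share = (weights[(col == lev).to_numpy()].sum() / total * 100.0
                     if total > 0 else np.nan)
            rows.append((str(lev), "share", share, np.nan))
        return rows
    obs = col.notna().to_numpy()
    if not obs.any():
        return [("mean", "metric", np.nan, np.nan)]
    m, sd = _wmean_sd(col.to_numpy(dtype=float)[obs], weights[obs])
    return [("mean", "metric", m, sd)]


def balance_table(
    table: pd.DataFrame,
    final_weights: np.ndarray,
    variables: list[str],
    strata: str | None = None,
) -> pd.DataFrame:
    """Four-column comparison of variable distributions.

    Columns: whole baseline sample and nonrespondents under baseline
    weights, respondents under baseline weights, respondents under the
    longitudinal weights.  ``final_weights`` aligns with the respondent
    rows in table order.  Categorical variables appear as level shares in
    percent, metric ones as mean with sd.  With ``strata`` (a column name),
    every block is additionally computed within each stratum; empty strata
    are flagged, not dropped.
    """
    for v in variables:
        if v not in table.columns:
            raise KeyError(f"variable {v!r} not in table")
    resp = table["response"].to_numpy() == 1
    if len(np.asarray(final_weights)) != int(resp.sum()):
        raise ValueError("final_weights must align with respondent rows")
    base_w = table["baseline_weight"].to_numpy(dtype=float)
    long_w = np.asarray(final_weights, dtype=float)

    groups: list[tuple[str, pd.DataFrame, np.ndarray]] = [
        ("whole_sample", table, base_w),
        ("nonrespondents", table[~resp], base_w[~resp]),
        ("respondents_baseline_w", table[resp], base_w[resp]),
        ("respondents_longitudinal_w", table[resp], long_w),
    ]

    strata_values: list[object] = ["all"]
    if strata is not None:
        strata_values += list(
            table[strata].cat.categories
            if isinstance(table[strata].dtype, pd.CategoricalDtype)
            else pd.unique(table[strata].dropna()))

    records = []
    for sv in strata_values:
        for variable in variables:
            rows: dict[tuple[str, str], dict] = {}
            for gname, sub, gw in groups:
                if sv == "all":
                    mask = np.ones(len(sub), dtype=bool)
                else:
                    mask = (sub[strata] == sv).to_numpy()
                empty = not mask.any()
                stats = (_column_stats(sub[mask], gw[mask], variable)
                         if not empty
                         else [(lev, kind, np.nan, np.nan) for lev, kind, *_ in
                               _column_stats(sub, gw, variable)])
                for lev, kind, val, sd in stats:
                    rec = rows.setdefault((lev, kind), {
                        "stratum": str(sv), "variable": variable,
                        "level": lev, "kind": kind, "empty_stratum": empty})
                    rec[gname] = val
                    rec[f"sd_{gname}"] = sd
                    rec["empty_stratum"] = rec["empty_stratum"] or empty
            records.extend(rows.values())
    df = pd.DataFrame.from_records(records)
    order = ["stratum", "variable", "level", "kind",
             "whole_sample", "nonrespondents", "respondents_baseline_w",
             "respondents_longitudinal_w",
             "sd_whole_sample", "sd_nonrespondents",
             "sd_respondents_baseline_w", "sd_respondents_longitudinal_w",
             "empty_stratum"]
    return df[order]


def bias_reduction_summary(balance: pd.DataFrame) -> pd.DataFrame:
    """Percent of the pre-weighting bias removed, per balance-table row.

    Bias is measured against the whole-sample column; negative values mean
    the weighting amplified the gap and are reported as-is.  Rows with zero
    pre-weighting bias are flagged undefined.
    """
    out = balance.loc[:, ["stratum", "variable", "level", "kind"]].copy()
    before = balance["respondents_baseline_w"] - balance["whole_sample"]
    after = balance["respondents_longitudinal_w"] - balance["whole_sample"]
    out["bias_before"] = before
    out["bias_after"] = after
    undefined = before == 0
    out["undefined"] = undefined | balance["empty_stratum"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_bias_removed"] = 100.0 * (1.0 - after.abs() / before.abs())
    out.loc[out["undefined"], "pct_bias_removed"] = np.nan
    return out


def diagnostics_report(
    table: pd.DataFrame,
    final_weights: np.ndarray,
    variables: list[str],
    strata: str | None = None,
    variance_method: str = "linearization",
    seed: int = 0,
) -> dict:
    """Assemble the full diagnostics bundle for a weighted cohort.

    ``table`` is the baseline subject table (with ``response`` and
    ``baseline_weight``); ``final_weights`` the standardized longitudinal
    weights of the respondents.  Per-variable estimator-variance ratios are
    computed on metric variables among respondents.
    """
    w = np.asarray(final_weights, dtype=float)
    resp = table["response"].to_numpy() == 1
    balance = balance_table(table, w, variables, strata)
    bias = bias_reduction_summary(balance)
    ratios = {}
    for v in variables:
        col = table.loc[resp, v]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
                col.dtype, pd.CategoricalDtype):
            obs = col.notna().to_numpy()
            r = estimator_variance_ratio(
                col.to_numpy(dtype=float)[obs], w[obs],
                method=variance_method, seed=seed)
            ratios[v] = {"ratio": r,
                         "pct_increase": 100.0 * (r - 1.0)
                         if np.isfinite(r) else None}
    return {
        "efficiency_pct": kish_efficiency(w),
        "variance_inflation": variance_inflation(w),
        "weight_range": [float(w.min()), float(w.max())],
        "n_responders": int(len(w)),
        "estimator_variance_ratios": ratios,
        "balance": balance.to_dict(orient="records"),
        "bias_summary": bias.to_dict(orient="records"),
    }


def truth_recovery(
    table: pd.DataFrame,
    final_weights: np.ndarray,
    true_means: dict[str, float],
) -> dict:
    """Compare respondent outcome means, weighted and unweighted, to truth.

    Only meaningful on synthetic cohorts, where the full-cohort outcome
    means are known.  For each outcome reports the absolute error of the
    unweighted and the weighted respondent mean and whether weighting moved
    the estimate closer to the full-cohort value.
    """
    resp = table["response"].to_numpy() == 1
    w = np.asarray(final_weights, dtype=float)
    out = {}
    for name, truth in true_means.items():
        x = table.loc[resp, name].to_numpy(dtype=float)
        unw = float(x.mean())
        wtd = float(np.average(x, weights=w))
        out[name] = {
            "truth": float(truth),
            "unweighted_mean": unw,
            "weighted_mean": wtd,
            "abs_error_unweighted": abs(unw - truth),
            "abs_error_weighted": abs(wtd - truth),
            "improved": abs(wtd - truth) < abs(unw - truth),
        }
    return out


def format_diagnostics(report: dict) -> str:
    lines = [
        f"Weighting efficiency: {report['efficiency_pct']:.2f}%",
        f"Variance inflation factor: {report['variance_inflation']:.3f}",
        "Weight range: {:.2f} to {:.2f}".format(*report["weight_range"]),
        f"Responders: {report['n_responders']}",
    ]
    if report["estimator_variance_ratios"]:
        lines.append("Estimator variance increase (weighted vs unweighted):")
        for v, r in report["estimator_variance_ratios"].items():
            if r["pct_increase"] is None:
                lines.append(f"  {v}: undefined (zero unweighted variance)")
            else:
                lines.append(f"  {v}: {r['pct_increase']:+.1f}%")
    return "\n".join(lines)
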