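"""Covariate preparation: categorization, missing levels, design matrices.

The nonresponse models downstream work on an all-categorical representation
of the candidate covariates.  Metric covariates are cut into categories —
by substantively meaningful cutpoints where they exist (e.g. BMI classes),
otherwise into five weighted-percentile groups — and every covariate gets
an explicit last level ``"missing"`` so that item nonresponse (which cannot
be assumed MCAR/MAR, e.g. income refused preferentially at the extremes)
participates in the model like any other level instead of dropping rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING_LEVEL",
    "CategorizationRule",
    "DesignColumn",
    "DesignMatrix",
    "DegenerateCovariateError",
    "weighted_quantile",
    "categorize",
    "add_missing_level",
    "filter_by_availability",
    "build_design_matrix",
    "prepare_covariates",
]

#: Reserved level name appended (last) to every covariate's level inventory.
MISSING_LEVEL = "missing"


class DegenerateCovariateError(ValueError):
    """Raised when a covariate cannot support the requested categorization."""


@dataclass(frozen=True)
class CategorizationRule:
    """How to turn one metric covariate into a categorical one.

    mode='practical': half-open bins over explicit ``cutpoints``
    (lowest bin open below, highest open above), k cutpoints -> k+1 levels.
    mode='quintile': five groups cut at the weighted 20/40/60/80th
    percentiles of the non-missing values; boundary values go to the lower
    group.
    """

    covariate: str
    mode: str = "quintile"
    cutpoints: tuple[float, ...] | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("practical", "quintile"):
            raise ValueError(f"unknown categorization mode {self.mode!r}")
        if self.mode == "practical":
            if not self.cutpoints:
                raise ValueError("practical mode needs at least one cutpoint")
            cp = tuple(float(c) for c in self.cutpoints)
            if any(a >= b for a, b in zip(cp, cp[1:])):
                raise ValueError("cutpoints must be strictly increasing")
            if self.labels is not None and len(self.labels) != len(cp) + 1:
                raise ValueError("need len(cutpoints)+1 labels")


def weighted_quantile(
    values: np.ndarray, q: float | np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted lower-interpolation quantile (inverse-CDF, type 1).

    The q-quantile is the smallest observed value whose cumulative weight
    share reaches q.  With unit weights this reduces to
    ``np.percentile(..., method='inverted_cdf')``.
    """
    values = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile levels must lie in [0, 1]")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    if total <= 0:
        raise ValueError("total weight must be positive")
    idx = np.searchsorted(cw / total, q, side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    return v[idx]


def categorize(
    values,
    rule: CategorizationRule,
    weights: np.ndarray | None = None,
) -> pd.Categorical:
    """Cut a metric vector into ordered categories per ``rule``.

    Missing entries map to the reserved ``"missing"`` level (always last in
    the level inventory).  Quintile cuts use the weighted percentiles of the
    non-missing values, with boundary values assigned to the lower group.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    obs = values.notna().to_numpy()
    x = values.to_numpy()

    if rule.mode == "practical":
        cut = np.asarray(rule.cutpoints, dtype=float)
        labels = list(rule.labels) if rule.labels else [
            f"[{lo}, {hi})" for lo, hi in zip(
                ["-inf", *map(str, cut)], [*map(str, cut), "inf"])
        ]
        # half-open [c_i, c_{i+1}); below the first cutpoint -> level 0
        codes = np.searchsorted(cut, x[obs], side="right")
    else:
        xo = x[obs]
        if len(np.unique(xo)) < 5:
            raise DegenerateCovariateError(
                f"covariate {rule.covariate!r}: quintile categorization needs "
                f">=5 distinct non-missing values"
            )
        wo = None if weights is None else np.asarray(weights, dtype=float)[obs]
        qs = weighted_quantile(xo, [0.2, 0.4, 0.6, 0.8], wo)
        labels = list(rule.labels) if rule.labels else [
            "q1", "q2", "q3", "q4", "q5"]
        # right-closed bins: boundary values fall in the lower group
        codes = np.searchsorted(qs, xo, side="left")

    all_codes = np.full(len(x), len(labels), dtype=int)  # missing sentinel
    all_codes[obs] = codes
    return pd.Categorical.from_codes(
        all_codes, categories=[*labels, MISSING_LEVEL], ordered=False
    )


def add_missing_level(table: pd.DataFrame, covariate: str) -> pd.DataFrame:
    """Replace missing entries of ``covariate`` with the explicit level.

    Returns a copy; the column becomes categorical with ``"missing"``
    recorded as the last level.  A column left with a single level is kept
    but will be flagged degenerate at design-matrix time.
    """
    if covariate not in table.columns:
        raise KeyError(f"unknown covariate {covariate!r}")
    out = table.copy()
    col = out[covariate]
    if not isinstance(col.dtype, pd.CategoricalDtype):
        observed = col.dropna().unique()
        col = pd.Categorical(col, categories=[str(c) for c in observed]
                             if col.dtype == object else list(observed))
        col = pd.Series(col, index=out.index)
    cats = [c for c in col.cat.categories if c != MISSING_LEVEL]
    col = col.cat.set_categories([*cats, MISSING_LEVEL])
    col = col.fillna(MISSING_LEVEL)
    out[covariate] = col
    return out


def filter_by_availability(
    table: pd.DataFrame, covariates: list[str], threshold: float = 1.0
) -> list[str]:
    """Keep covariates observed in at least ``threshold`` of subjects.

    With the default 1.0 only covariates measured in every subject survive,
    mirroring a preliminary screen that removes items not fielded to the
    whole sample before missing categories are defined.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    kept = []
    for c in covariates:
        frac = table[c].notna().mean()
        if frac >= threshold:
            kept.append(c)
        else:
            logger.info("dropping %r: observed fraction %.3f < %.3f",
                        c, frac, threshold)
    return kept


@dataclass(frozen=True)
class DesignColumn:
    covariate: str
    level: str

    @property
    def name(self) -> str:
        return f"{self.covariate}={self.level}"


@dataclass
class DesignMatrix:
    """0/1 indicator encoding, one column per non-reference level.

    Rows align with the source subject table.  ``reference`` maps each
    covariate to its baseline level (odds ratio 1.00 by convention).
    """

    X: np.ndarray
    columns: list[DesignColumn]
    reference: dict[str, str]
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.covariates:
            seen: list[str] = []
            for c in self.columns:
                if c.covariate not in seen:
                    seen.append(c.covariate)
            self.covariates = seen

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def column_indices(self, covariate: str) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.covariate == covariate]

    def restrict(self, covariates: list[str]) -> "DesignMatrix":
        """View on a subset of covariates, preserving declaration order."""
        keep = [i for i, c in enumerate(self.columns) if c.covariate in covariates]
        return DesignMatrix(
            X=self.X[:, keep],
            columns=[self.columns[i] for i in keep],
            reference={c: self.reference[c] for c in covariates
                       if c in self.reference},
            covariates=[c for c in self.covariates if c in covariates],
        )

    def subset_rows(self, mask: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(self.X[mask], self.columns, self.reference,
                            list(self.covariates))


def build_design_matrix(
    table: pd.DataFrame,
    covariates: list[str],
    references: dict[str, str] | None = None,
    drop_degenerate: bool = True,
) -> DesignMatrix:
    """Indicator-encode categorical covariates (k levels -> k-1 columns).

    The reference level defaults to the first declared level of each
    covariate; columns follow covariate declaration order, then level order,
    so the encoding is deterministic.  Single-level covariates are excluded
    with a warning rather than failing the pipeline; pass
    ``drop_degenerate=False`` for prediction-time designs whose rows need
    not span every level.
    """
    references = dict(references or {})
    cols: list[DesignColumn] = []
    arrays: list[np.ndarray] = []
    used: list[str] = []
    ref_out: dict[str, str] = {}
    for cov in covariates:
        s = table[cov]
        if not isinstance(s.dtype, pd.CategoricalDtype):
            raise TypeError(
                f"covariate {cov!r} is not categorical; run add_missing_level"
                " / categorize first")
        levels = [str(l) for l in s.cat.categories]
        if drop_degenerate and (len(levels) < 2 or s.nunique() < 2):
            warnings.warn(
                f"covariate {cov!r} is degenerate (single level); excluded "
                "from the design", UserWarning, stacklevel=2)
            continue
        ref = references.get(cov, levels[0])
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} not among levels of {cov!r}: {levels}")
        codes = s.cat.codes.to_numpy()
        for li, lev in enumerate(levels):
            if lev == ref:
                continue
            ind = (codes == li).astype(float)
            if drop_degenerate and ind.sum() == 0:
                continue  # unobserved level: an all-zero column fits nothing
            cols.append(DesignColumn(cov, lev))
            arrays.append(ind)
        used.append(cov)
        ref_out[cov] = ref
    X = np.column_stack(arrays) if arrays else np.empty((len(table), 0))
    return DesignMatrix(X=X, columns=cols, reference=ref_out, covariates=used)


def prepare_covariates(
    table: pd.DataFrame,
    covariates: list[str],
    rules: dict[str, CategorizationRule] | None = None,
    baseline_weights: np.ndarray | None = None,
    availability_threshold: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Full prep: availability screen, categorize metrics, add missing levels.

    Returns the prepared table (all listed covariates categorical with an
    explicit missing level) and the list of retained covariate names.
    Metric covariates without a rule get the quintile default; quintile cuts
    use the baseline weights when provided.
    """
    rules = dict(rules or {})
    if availability_threshold is not None:
        covariates = filter_by_availability(table, covariates,
                                            availability_threshold)
    out = table.copy()
    kept: list[str] = []
    for cov in covariates:
        col = out[cov]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
                col.dtype, pd.CategoricalDtype):
            rule = rules.get(cov, CategorizationRule(cov, "quintile"))
            try:
                out[cov] = categorize(col.to_numpy(), rule, baseline_weights)
            except DegenerateCovariateError as exc:
                warnings.warn(str(exc), UserWarning, stacklevel=2)
                continue
        out = add_missing_level(out, cov)
        kept.append(cov)
    return out, kept
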