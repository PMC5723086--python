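"""Step 3 — combine, trim and standardize the longitudinal weights.

Respondents' raw inverse-probability weights (1/PRED) are multiplied by
their baseline design weights, the products are winsorized at the 0.5 and
99.5 percentiles (capped, not deleted, so the respondent count is
preserved), and the result is divided by its mean so the final weights
average one and sum to the number of respondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .propensity_ipw import inverse_probability

__all__ = [
    "WeightSet",
    "combine_weights",
    "trim_weights",
    "standardize_weights",
    "finalize",
]


@dataclass
class WeightSet:
    """Per-responder weights at every stage of step 3."""

    raw_ipw: np.ndarray
    combined: np.ndarray
    trimmed: np.ndarray
    standardized: np.ndarray
    lower_pct: float
    upper_pct: float
    lower_cut: float
    upper_cut: float

    @property
    def n_responders(self) -> int:
        return len(self.standardized)

    def summary(self) -> dict:
        w = self.standardized
        return {
            "n_responders": self.n_responders,
            "min": float(w.min()),
            "max": float(w.max()),
            "mean": float(w.mean()),
            "trim_percentiles": [self.lower_pct, self.upper_pct],
            "trim_cutoffs": [self.lower_cut, self.upper_cut],
        }


def _check_positive(w: np.ndarray, name: str) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return w


def combine_weights(raw_ipw: np.ndarray, baseline_weights: np.ndarray) -> np.ndarray:
    """Elementwise product of inverse-probability and baseline weights."""
    raw = _check_positive(raw_ipw, "raw_ipw")
    base = _check_positive(baseline_weights, "baseline_weights")
    if raw.shape != base.shape:
        raise ValueError(
            f"weight vectors not aligned: {raw.shape} vs {base.shape}")
    return raw * base


def trim_weights(
    combined: np.ndarray,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
) -> tuple[np.ndarray, float, float]:
    """Winsorize at the given percentiles (lower-interpolation).

    Values beyond a cutoff are set to it; no subject is dropped, so the
    sample size survives the trim.  Returns (trimmed, lower, upper cutoff).
    """
    if not 0.0 <= lower_pct < upper_pct <= 100.0:
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    w = _check_positive(combined, "combined weights")
    lo = float(np.percentile(w, lower_pct, method="lower"))
    hi = float(np.percentile(w, upper_pct, method="lower"))
    return np.clip(w, lo, hi), lo, hi


def standardize_weights(trimmed: np.ndarray) -> np.ndarray:
    """Divide by the mean: final weights average 1 and sum to n."""
    w = _check_positive(trimmed, "trimmed weights")
    return w / w.mean()


def finalize(
    pred: np.ndarray,
    baseline_weights: np.ndarray,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
) -> WeightSet:
    """Full step 3 for respondent rows: 1/PRED -> combine -> trim -> mean-1.

    ``pred`` and ``baseline_weights`` must already be restricted to
    respondents — nonrespondents carry no longitudinal weight.
    """
    raw = inverse_probability(pred)
    combined = combine_weights(raw, baseline_weights)
    trimmed, lo, hi = trim_weights(combined, lower_pct, upper_pct)
    standardized = standardize_weights(trimmed)
    return WeightSet(
        raw_ipw=raw, combined=combined, trimmed=trimmed,
        standardized=standardized, lower_pct=lower_pct, upper_pct=upper_pct,
        lower_cut=lo, upper_cut=hi,
    )
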