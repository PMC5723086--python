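"""Synthetic two-wave cohorts with a known drop-out mechanism.

Generates baseline cohorts in which wave-1 participation follows a logistic
model on categorical covariates with user-chosen odds ratios, baseline
design weights follow a modest-dispersion lognormal, metric outcomes are
linear in dropout-predictor levels (so dropout biases respondent means),
and covariate missingness can be MCAR or "extreme" NMAR (blanked
preferentially at the tails of the underlying metric value, the way income
questions are refused at very low and very high incomes).

Categorical covariates are produced by cutting a latent standard-normal
variable at quantile cutpoints, so every categorical covariate has a
well-defined "extreme" for NMAR blanking to act on.  Missingness is applied
after the response indicator is drawn and therefore never alters the true
participation mechanism; the pre-blanking table is retained for oracle
checks.

The shipped :func:`realism_preset` mimics a two-wave youth cohort of ~4,500
subjects with ~62% wave-1 response and dropout odds ratios spanning roughly
0.02–1.7 across social, household, media, behavioural and health themes.
The preset's odds ratios are illustrative defaults, not estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ConfigurationError",
    "CovariateSpec",
    "MissingnessRule",
    "OutcomeSpec",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "apply_missingness",
    "calibrate_intercept",
    "realism_preset",
    "write_cohort",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """An invalid cohort/scenario configuration."""


@dataclass(frozen=True)
class CovariateSpec:
    """One candidate covariate.

    Categorical covariates are cut from a latent N(0,1) at the quantile
    cutpoints implied by ``probs``; metric covariates are drawn from
    ``dist`` = (family, *params), family in {normal, uniform, lognormal}.
    """

    name: str
    theme: str
    kind: str = "categorical"
    levels: tuple[str, ...] | None = None
    probs: tuple[float, ...] | None = None
    dist: tuple = ("normal", 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "metric"):
            raise ConfigurationError(
                f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels or not self.probs:
                raise ConfigurationError(
                    f"covariate {self.name!r}: categorical needs levels+probs")
            if len(self.levels) != len(self.probs):
                raise ConfigurationError(
                    f"covariate {self.name!r}: levels/probs length mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-8 or min(self.probs) <= 0:
                raise ConfigurationError(
                    f"covariate {self.name!r}: probs must be positive and sum"
                    " to 1")


@dataclass(frozen=True)
class MissingnessRule:
    """Covariate blanking rule: none, MCAR(rate), or extreme-NMAR.

    extreme_nmar blanks with probability ``rate`` only among rows whose
    underlying metric value (the latent, for categorical covariates) lies
    below the ``lower_q`` or above the ``upper_q`` quantile.
    """

    covariate: str
    kind: str = "mcar"
    rate: float = 0.0
    lower_q: float = 0.1
    upper_q: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in ("none", "mcar", "extreme_nmar"):
            raise ConfigurationError(f"unknown missingness kind {self.kind!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ConfigurationError(
                f"missingness rate for {self.covariate!r} outside [0, 1]")
        if not 0.0 <= self.lower_q < self.upper_q <= 1.0:
            raise ConfigurationError(
                f"quantile band for {self.covariate!r} invalid")


@dataclass(frozen=True)
class OutcomeSpec:
    """Metric outcome: intercept + level effects + Gaussian noise."""

    name: str
    intercept: float
    coefs: dict = field(default_factory=dict)  # covariate -> {level: effect}
    noise_sd: float = 1.0


@dataclass
class CohortConfig:
    """Full data-generating configuration for one synthetic cohort."""

    n_subjects: int
    seed: int
    covariates: list[CovariateSpec]
    dropout_intercept: float = 0.0
    dropout_coefs: dict = field(default_factory=dict)  # cov -> {level: logOR}
    missingness: list[MissingnessRule] = field(default_factory=list)
    baseline_weight_sigma: float = 0.35
    outcomes: list[OutcomeSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.baseline_weight_sigma < 0:
            raise ConfigurationError("baseline_weight_sigma must be >= 0")
        by_name = {c.name: c for c in self.covariates}
        if len(by_name) != len(self.covariates):
            raise ConfigurationError("duplicate covariate names")
        for cov, levels in self.dropout_coefs.items():
            spec = by_name.get(cov)
            if spec is None:
                raise ConfigurationError(
                    f"dropout_coefs references unknown covariate {cov!r}")
            for lev in levels:
                if spec.kind == "categorical" and lev not in spec.levels:
                    raise ConfigurationError(
                        f"dropout_coefs references unknown level {lev!r} of"
                        f" covariate {cov!r}")
        for rule in self.missingness:
            if rule.covariate not in by_name:
                raise ConfigurationError(
                    f"missingness rule references unknown covariate"
                    f" {rule.covariate!r}")
        for out in self.outcomes:
            for cov in out.coefs:
                if cov not in by_name:
                    raise ConfigurationError(
                        f"outcome {out.name!r} references unknown covariate"
                        f" {cov!r}")

    @property
    def theme_map(self) -> dict[str, list[str]]:
        themes: dict[str, list[str]] = {}
        for c in self.covariates:
            themes.setdefault(c.theme, []).append(c.name)
        return themes


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth.

    ``table`` is the analyst-facing subject table (missingness applied);
    ``complete_table`` retains the pre-blanking values for oracle checks.
    ``true_outcome_means`` are full-cohort means — the estimand the
    weighting procedure tries to recover from respondents alone.
    """

    table: pd.DataFrame
    complete_table: pd.DataFrame
    true_response_probability: np.ndarray
    true_outcome_means: dict[str, float]
    config: CohortConfig
    latents: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def response_rate(self) -> float:
        return float(self.table["response"].mean())


def _draw_metric(spec: CovariateSpec, rng: np.random.Generator, n: int):
    family, *params = spec.dist
    if family == "normal":
        return rng.normal(params[0], params[1], n)
    if family == "uniform":
        return rng.uniform(params[0], params[1], n)
    if family == "lognormal":
        return rng.lognormal(params[0], params[1], n)
    raise ConfigurationError(
        f"covariate {spec.name!r}: unknown distribution family {family!r}")


def _linear_predictor(config: CohortConfig, levels: dict[str, np.ndarray],
                      n: int) -> np.ndarray:
    lp = np.full(n, config.dropout_intercept, dtype=float)
    for cov, coefs in config.dropout_coefs.items():
        vals = levels[cov]
        for lev, beta in coefs.items():
            lp += np.where(vals == lev, float(beta), 0.0)
    return lp


def generate_cohort(config: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate one cohort; bit-identical under the same (config, seed)."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_subjects

    latents: dict[str, np.ndarray] = {}
    levels: dict[str, np.ndarray] = {}
    data: dict[str, object] = {}
    for spec in config.covariates:
        if spec.kind == "categorical":
            z = rng.standard_normal(n)
            cuts = norm.ppf(np.cumsum(spec.probs)[:-1])
            codes = np.searchsorted(cuts, z, side="left")
            latents[spec.name] = z
            vals = np.asarray(spec.levels, dtype=object)[codes]
            levels[spec.name] = vals
            data[spec.name] = pd.Categorical(vals, categories=list(spec.levels))
        else:
            x = _draw_metric(spec, rng, n)
            latents[spec.name] = x
            data[spec.name] = x

    lp = _linear_predictor(config, levels, n)
    true_p = expit(lp)
    response = (rng.random(n) < true_p).astype(int)

    sigma = config.baseline_weight_sigma
    baseline_weight = (rng.lognormal(-0.5 * sigma**2, sigma, n)
                       if sigma > 0 else np.ones(n))

    outcomes: dict[str, np.ndarray] = {}
    for out in config.outcomes:
        y = np.full(n, out.intercept, dtype=float)
        for cov, coefs in out.coefs.items():
            vals = levels.get(cov, latents.get(cov))
            for lev, effect in coefs.items():
                y += np.where(np.asarray(vals, dtype=object) == lev,
                              float(effect), 0.0)
        if out.noise_sd > 0:
            y += rng.normal(0.0, out.noise_sd, n)
        outcomes[out.name] = y

    width = len(str(n))
    table = pd.DataFrame({
        "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
        "baseline_weight": baseline_weight,
        "response": response,
        **data,
        **outcomes,
    })
    true_means = {name: float(vals.mean()) for name, vals in outcomes.items()}

    cohort = SyntheticCohort(
        table=table,
        complete_table=table.copy(),
        true_response_probability=true_p,
        true_outcome_means=true_means,
        config=config,
        latents=latents,
    )
    if config.missingness:
        cohort = apply_missingness(cohort, config.missingness, rng=rng)
    return cohort


def apply_missingness(
    cohort: SyntheticCohort,
    rules: list[MissingnessRule],
    rng: np.random.Generator | None = None,
) -> SyntheticCohort:
    """Blank covariate entries per the rules; the truth stays untouched.

    Blanking happens strictly after the response indicator was drawn, so the
    participation mechanism is unchanged; ``complete_table`` keeps the
    original values.  A fresh deterministic stream is derived from the
    config seed when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [cohort.config.seed, 0x6D69_7373]))
    table = cohort.table.copy()
    known = set(c.name for c in cohort.config.covariates) | set(table.columns)
    for rule in rules:
        if rule.covariate not in known:
            raise ConfigurationError(
                f"missingness rule references unknown covariate"
                f" {rule.covariate!r}")
        if rule.kind == "none" or rule.rate == 0.0:
            continue
        col = table[rule.covariate]
        n = len(col)
        if rule.kind == "mcar":
            blank = rng.random(n) < rule.rate
        else:
            base = cohort.latents.get(rule.covariate)
            if base is None:
                base = pd.to_numeric(cohort.complete_table[rule.covariate])
                base = np.asarray(base, dtype=float)
            lo = np.quantile(base, rule.lower_q)
            hi = np.quantile(base, rule.upper_q)
            extreme = (base < lo) | (base > hi)
            blank = extreme & (rng.random(n) < rule.rate)
        if isinstance(col.dtype, pd.CategoricalDtype):
            codes = col.cat.codes.to_numpy().copy()
            codes[blank] = -1
            table[rule.covariate] = pd.Categorical.from_codes(
                codes, categories=col.cat.categories)
        else:
            vals = col.to_numpy(dtype=float).copy()
            vals[blank] = np.nan
            table[rule.covariate] = vals
    return SyntheticCohort(
        table=table,
        complete_table=cohort.complete_table,
        true_response_probability=cohort.true_response_probability,
        true_outcome_means=cohort.true_outcome_means,
        config=cohort.config,
        latents=cohort.latents,
    )


def calibrate_intercept(
    config: CohortConfig,
    target_rate: float,
    n_mc: int = 200_000,
    mc_seed: int = 20_170_101,
) -> float:
    """Intercept giving the target marginal response rate.

    Solves E[logistic(b0 + lp)] = target over the covariate distribution by
    Monte-Carlo integration (fixed internal seed, so the calibration is
    deterministic) and root bracketing.
    """
    if not 0.0 < target_rate < 1.0:
        raise ConfigurationError("target_rate must lie in (0, 1)")
    rng = np.random.default_rng(mc_seed)
    levels: dict[str, np.ndarray] = {}
    for spec in config.covariates:
        if spec.kind == "categorical" and spec.name in config.dropout_coefs:
            codes = rng.choice(len(spec.levels), size=n_mc, p=spec.probs)
            levels[spec.name] = np.asarray(spec.levels, dtype=object)[codes]
    base = config.dropout_intercept
    lp = _linear_predictor(config, levels, n_mc) - base

    def gap(b0: float) -> float:
        return float(expit(b0 + lp).mean()) - target_rate

    return float(brentq(gap, -20.0, 20.0, xtol=1e-6))


# ---------------------------------------------------------------------------
# Shipped realism preset
# ---------------------------------------------------------------------------

def _lor(x: float) -> float:
    return float(np.log(x))


def realism_preset(
    n_subjects: int = 4500,
    seed: int = 0,
    target_response_rate: float = 0.62,
) -> CohortConfig:
    """Two-wave youth-cohort scenario with illustrative dropout odds ratios.

    Twelve categorical covariates across six context themes; odds ratios
    span ~0.02 (very heavy daily TV use) to ~1.7 (fluoride toothpaste),
    with strong social gradients (low socioeconomic status 0.22, low
    maternal education 0.33).  Household income is blanked NMAR at the
    extremes of its latent scale; several covariates get light MCAR
    missingness.  Outcomes (a BMI-like and a motor-performance-like score)
    load on dropout predictors, so respondent means are biased before
    weighting.  The intercept is calibrated so the marginal response rate
    is ~62%.
    """
    q5 = ("q81-100", "q61-80", "q41-60", "q21-40", "q1-20")
    covs = [
        CovariateSpec("sex", "demographics", levels=("female", "male"),
                      probs=(0.487, 0.513)),
        CovariateSpec("age_group", "demographics",
                      levels=("4-5", "6-10", "11-13", "14-17"),
                      probs=(0.13, 0.36, 0.21, 0.30)),
        CovariateSpec("ses", "social", levels=q5,
                      probs=(0.2, 0.2, 0.2, 0.2, 0.2)),
        CovariateSpec("income", "social", levels=q5,
                      probs=(0.2, 0.2, 0.2, 0.2, 0.2)),
        CovariateSpec("mother_edu", "social",
                      levels=("high", "moderate", "low"),
                      probs=(0.30, 0.45, 0.25)),
        CovariateSpec("smoking_home", "household", levels=("no", "yes"),
                      probs=(0.70, 0.30)),
        CovariateSpec("language_home", "household", levels=("same", "other"),
                      probs=(0.85, 0.15)),
        CovariateSpec("bmi_group", "health",
                      levels=("underweight", "normal", "overweight", "obese"),
                      probs=(0.08, 0.62, 0.20, 0.10)),
        CovariateSpec("adhs", "health", levels=("no", "unknown", "yes"),
                      probs=(0.90, 0.03, 0.07)),
        CovariateSpec("tv_daily", "media",
                      levels=("0h", "<1h", "1.5h", "3-4h", "5h+"),
                      probs=(0.08, 0.40, 0.32, 0.15, 0.05)),
        CovariateSpec("bike_helmet", "behaviour",
                      levels=("yes", "no", "no_bike"),
                      probs=(0.55, 0.35, 0.10)),
        CovariateSpec("outings", "behaviour",
                      levels=("always", "sometimes", "rarely", "never"),
                      probs=(0.35, 0.40, 0.17, 0.08)),
    ]
    dropout = {
        "sex": {"male": _lor(0.84)},
        "age_group": {"6-10": _lor(1.10), "11-13": _lor(0.63),
                      "14-17": _lor(0.55)},
        "ses": {"q61-80": _lor(0.86), "q41-60": _lor(0.62),
                "q21-40": _lor(0.47), "q1-20": _lor(0.22)},
        "income": {"q61-80": _lor(0.90), "q41-60": _lor(0.72),
                   "q21-40": _lor(0.52), "q1-20": _lor(0.31)},
        "mother_edu": {"moderate": _lor(0.71), "low": _lor(0.33)},
        "smoking_home": {"yes": _lor(0.51)},
        "language_home": {"other": _lor(0.39)},
        "bmi_group": {"normal": _lor(1.02), "overweight": _lor(0.89),
                      "obese": _lor(0.39)},
        "adhs": {"unknown": _lor(0.82), "yes": _lor(0.53)},
        "tv_daily": {"<1h": _lor(0.63), "1.5h": _lor(0.34),
                     "3-4h": _lor(0.10), "5h+": _lor(0.02)},
        "bike_helmet": {"no": _lor(0.45), "no_bike": _lor(0.34)},
        "outings": {"sometimes": _lor(0.88), "rarely": _lor(0.54),
                    "never": _lor(0.47)},
    }
    missing = [
        MissingnessRule("income", "extreme_nmar", rate=0.30,
                        lower_q=0.10, upper_q=0.90),
        MissingnessRule("mother_edu", "mcar", rate=0.03),
        MissingnessRule("tv_daily", "mcar", rate=0.04),
        MissingnessRule("bike_helmet", "mcar", rate=0.03),
        MissingnessRule("outings", "mcar", rate=0.03),
        MissingnessRule("adhs", "mcar", rate=0.05),
        MissingnessRule("bmi_group", "mcar", rate=0.02),
    ]
    outcomes = [
        OutcomeSpec("bmi_score", intercept=18.0, noise_sd=2.0, coefs={
            "bmi_group": {"underweight": -2.5, "overweight": 3.0,
                          "obese": 6.0},
            "ses": {"q21-40": 0.3, "q1-20": 0.6},
            "tv_daily": {"3-4h": 0.4, "5h+": 0.8},
            "age_group": {"6-10": 1.5, "11-13": 3.5, "14-17": 5.0},
        }),
        # age-normed motor quotient: loads on the social/behavioural dropout
        # predictors but not on age, like a standardized motor test score
        OutcomeSpec("motor_score", intercept=100.0, noise_sd=12.0, coefs={
            "ses": {"q61-80": -1.0, "q41-60": -2.0, "q21-40": -4.0,
                    "q1-20": -6.0},
            "tv_daily": {"1.5h": -2.0, "3-4h": -5.0, "5h+": -8.0},
            "bmi_group": {"obese": -10.0},
        }),
    ]
    config = CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        covariates=covs,
        dropout_intercept=0.0,
        dropout_coefs=dropout,
        missingness=missing,
        baseline_weight_sigma=0.35,
        outcomes=outcomes,
    )
    config.dropout_intercept = calibrate_intercept(config, target_response_rate)
    return config


def screening_scenario(
    n_subjects: int = 4000,
    seed: int = 0,
    n_true: int = 6,
    n_themes: int = 6,
    n_covariates: int = 30,
    effect_magnitudes: tuple[float, ...] = (1.2, 1.06, 0.92, 0.78, 0.64, 0.5),
    null: bool = False,
    target_response_rate: float = 0.62,
) -> CohortConfig:
    """Benchmark scenario for the screening stage: known signal vs. noise.

    Binary covariates spread over themes; the first covariate of each of
    the first ``n_true`` themes carries a dropout log-odds-ratio of
    alternating sign (magnitudes from ``effect_magnitudes``), the rest are
    pure noise.  ``null=True`` zeroes every effect, giving a cohort whose
    participation is independent of all covariates.
    """
    if n_true > n_themes:
        raise ConfigurationError("need n_true <= n_themes")
    covs: list[CovariateSpec] = []
    prevalences = [0.2, 0.3, 0.4, 0.5]
    for i in range(n_covariates):
        theme = f"t{i % n_themes + 1}"
        p1 = prevalences[i % len(prevalences)]
        covs.append(CovariateSpec(
            f"x{i + 1:02d}", theme, levels=("a", "b"), probs=(1 - p1, p1)))
    dropout: dict = {}
    if not null:
        for t in range(n_true):
            mag = effect_magnitudes[t % len(effect_magnitudes)]
            sign = -1.0 if t % 2 == 0 else 1.0
            dropout[covs[t].name] = {"b": sign * mag}
    config = CohortConfig(
        n_subjects=n_subjects, seed=seed, covariates=covs,
        dropout_intercept=0.0, dropout_coefs=dropout,
        baseline_weight_sigma=0.35,
        outcomes=[OutcomeSpec(
            "outcome", intercept=0.0, noise_sd=1.0,
            coefs={} if null else {
                covs[t].name: {"b": 0.5} for t in range(n_true)})],
    )
    config.dropout_intercept = calibrate_intercept(
        config, target_response_rate)
    return config


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, csv_path, truth_path=None) -> None:
    """CSV table (missing as empty field) + JSON truth sidecar."""
    cohort.table.to_csv(csv_path, index=False)
    if truth_path is not None:
        truth = {
            "true_response_probability":
                np.round(cohort.true_response_probability, 10).tolist(),
            "true_outcome_means": cohort.true_outcome_means,
            "dropout_intercept": cohort.config.dropout_intercept,
            "dropout_coefs": cohort.config.dropout_coefs,
            "seed": cohort.config.seed,
            "n_subjects": cohort.config.n_subjects,
        }
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)


def _config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["covariates"] = [asdict(c) for c in config.covariates]
    d["missingness"] = [asdict(m) for m in config.missingness]
    d["outcomes"] = [asdict(o) for o in config.outcomes]
    return d


def save_config(config: CohortConfig, path) -> None:
    import yaml

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(_config_to_dict(config)), fh, sort_keys=False)


def load_config(path) -> CohortConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    covs = [CovariateSpec(
        name=c["name"], theme=c["theme"], kind=c.get("kind", "categorical"),
        levels=tuple(c["levels"]) if c.get("levels") else None,
        probs=tuple(c["probs"]) if c.get("probs") else None,
        dist=tuple(c.get("dist", ("normal", 0.0, 1.0))),
    ) for c in d["covariates"]]
    miss = [MissingnessRule(**m) for m in d.get("missingness", [])]
    outs = [OutcomeSpec(name=o["name"], intercept=o["intercept"],
                        coefs=o.get("coefs", {}),
                        noise_sd=o.get("noise_sd", 1.0))
            for o in d.get("outcomes", [])]
    config = CohortConfig(
        n_subjects=d["n_subjects"], seed=d["seed"], covariates=covs,
        dropout_intercept=d.get("dropout_intercept", 0.0),
        dropout_coefs=d.get("dropout_coefs", {}),
        missingness=miss,
        baseline_weight_sigma=d.get("baseline_weight_sigma", 0.35),
        outcomes=outs,
    )
    config.validate()
    return config
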