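# Methods

`longipw` implements a three-step inverse-probability-of-participation
weighting (IPW) procedure against drop-out bias in two-wave cohort
studies, together with the diagnostics needed to judge what the weights
cost and what they bought. This note describes the statistical model, the
procedure's tunable parameters, the synthetic cohorts used for
validation, and the numerical and design choices that were genuinely
open.

## The problem and the model

A baseline cohort of n subjects carries design weights d_i > 0 (from the
original survey's sampling and post-stratification) and a binary wave-1
participation indicator R_i. When participation is *not missing at
random* (NMAR in the unit-nonresponse sense: dropping out correlates
with health, social position, behaviour), respondent-only estimates of
means and shares are biased for the baseline population. IPW repairs
this by modelling the participation propensity

    P(R_i = 1 | x_i) = logit^-1(b0 + x_i' b)

and weighting each *respondent* by d_i / PRED_i, where PRED_i is the
fitted probability. Nonrespondents receive no longitudinal weight. The
price is variance: for weights w scaled to mean one, an estimator's
variance inflates by the factor

    V_w = V_u (1 + s_w^2),

s_w^2 the (population) variance of the weights. The Kish weighting
efficiency 100 (Σw)^2 / (n Σw^2) is exactly 100 / (1 + s_w^2) under that
convention, so the two diagnostics are one number; the package asserts
this identity to 1e-9.

## The three steps

**Step 1 — screening.** Candidate covariates (everything observed at
baseline that might predict dropping out) are made categorical: metric
variables are cut at substantively meaningful cutpoints where those
exist (BMI classes), otherwise into five weighted-percentile groups, and
every covariate receives an explicit last level `missing`, because item
nonresponse is itself often NMAR (income refused at very low and very
high incomes) and deleting or imputing those rows would distort the
propensity model. Covariates are grouped into content-defined *context
themes*; within each theme an L1-penalized (LASSO) logistic model of
participation, weighted by the baseline weights and tuned by 10-fold
cross-validation, ranks covariates by their shrinkage-path exit point —
the largest penalty at which any of their level coefficients is still
nonzero — and keeps as "significant" those with a nonzero coefficient at
the CV-optimal penalty. Significant covariates are regrouped into merged
themes and re-ranked the same way. The candidate count is then fixed by
a forward AUC procedure: starting from the top three predictors of each
merged theme, covariates are added by rank, round-robin across themes;
each addition is kept only if the weighted in-sample AUC gain of an
unpenalized refit is significant in a one-sided paired subject-level
bootstrap (default 1000 draws, alpha = 0.05); the first failed addition
stops the growth.

**Step 2 — the final model.** The screened candidates enter one more
weighted LASSO-logistic model with 10-fold CV; covariates with any
nonzero level coefficient at the CV optimum form the final predictive
factor subset. Reported odds ratios, Wald confidence intervals and
p-values come from an unpenalized weighted refit on that subset
("relaxed" reporting): penalized coefficients are shrunken and carry no
usable standard errors. PRED is taken from the refit, which also
guarantees calibration-in-the-large (the weighted mean of PRED equals
the weighted response rate).

**Step 3 — trimming and standardization.** For respondents, raw weights
1/PRED are multiplied by the baseline weights, winsorized at the 0.5 and
99.5 percentiles (values beyond a cutoff are set to it — nobody is
deleted, so the respondent count is preserved), and divided by their
mean, so the final weights average one and sum to the number of
respondents.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_folds` | 10 | CV folds, response-stratified |
| `n_lambda` | 100 | log-spaced penalty grid, from the smallest all-zero penalty down to 1e-4 of it |
| `start_k` | 3 | top-ranked predictors per merged theme in the starting AUC model |
| `alpha` | 0.05 | one-sided level of the bootstrap ΔAUC test |
| `n_boot` | 1000 | bootstrap draws per ΔAUC test (minimum 200) |
| `trim_lower/upper` | 0.5 / 99.5 | winsorization percentiles on the combined weights |
| `clip_eps` | 1e-6 | probability clipping bound before inversion |
| `growth` | round_robin | cross-theme growth order (`global` = strict exit-point order) |

Clipping guards the arithmetic of 1/PRED; trimming governs the
statistics. Both are kept deliberately.

All randomness flows through three named seeds (cohort, cross-validation,
bootstrap); nothing is clock-seeded, and identical configuration plus
seeds reproduces every artifact bit for bit.

## The LASSO path solver

The screening stage needs hundreds of cross-validated 100-point penalty
paths per analysis (each 10-fold CV fits eleven full paths), so the
weighted logistic LASSO is solved by a warm-started IRLS +
coordinate-descent path engine written for exactly this access pattern:
the quadratic subproblems run in active-set dimension on a cached
weighted Gram matrix (refreshed only when the fitted probabilities have
drifted materially), KKT checks use the exact logistic gradient so zero
patterns are exact, and predictors are standardized by their weighted
standard deviation before penalization. The observation weights enter
every likelihood, CV deviance and AUC as frequency-style weights scaled
to mean one, which makes all results invariant to rescaling the baseline
weights. The test-suite verifies the solver coefficient-wise against an
independent L1 solver (liblinear at matched penalty) and checks that
path exit orders survive a 10x finer grid.

## The synthetic cohorts

No real cohort microdata ships with the package; validation runs on
generated cohorts whose dropout mechanism is known exactly.

The generator (`synthetic_cohort`) draws categorical covariates by
cutting latent standard normals at quantile cutpoints — so "extreme"
NMAR missingness has a well-defined extreme to act on — assigns each
subject a participation probability from a logistic model with
configured level log-odds-ratios, draws the response, and only then
applies missingness (MCAR, or extreme-NMAR: blanking at a given rate
only in the tails of the latent scale). Missingness therefore never
alters the true mechanism, and the pre-blanking table is retained for
oracle checks. Baseline weights are lognormal with mean one and
sigma = 0.35 — the modest dispersion of a post-stratified survey weight;
real weight distributions are study-specific, so the dispersion is a
configuration knob, not a claim. Outcomes are linear in
dropout-predictor levels plus Gaussian noise, so dropout biases
respondent means by construction and "truth" (the full-cohort mean) is
known.

The shipped `realism_preset` emulates a two-wave youth cohort: 4,500
subjects, intercept calibrated to a ~62% marginal response rate, twelve
categorical covariates in six themes with illustrative odds ratios
spanning ~0.02 (very heavy daily TV use) to ~1.7, strong social
gradients (low socioeconomic status 0.22, low maternal education 0.33),
NMAR-blanked income and light MCAR missingness elsewhere, and two
outcomes: a BMI-like score (loading on BMI class, social status, media
use and age) and an age-normed motor quotient (loading on the social and
behavioural dropout predictors but not on age, the way standardized
motor test batteries report performance).  Both outcomes load on dropout
predictors with a common net direction, so respondent means are biased
before weighting — the property the bias-reduction studies rely on. `screening_scenario` builds the
signal-vs-noise benchmark used by the acceptance suite: 30 binary
covariates in 6 themes, of which 6 (one per theme) carry log-odds-ratios
of alternating sign and magnitude 0.5–1.2, or none under `null=True`.

What the generator does **not** emulate: cluster sampling and design
effects, multi-wave monotone or non-monotone participation patterns,
time-varying covariates, structurally unmeasured items (variables
fielded to only part of the sample), and correlated covariates beyond
what the shared dropout mechanism induces. Passing tests therefore show
that the procedure recovers a known single-wave NMAR mechanism with
independent covariates; they do not certify behaviour under clustered
designs or longer panels.

## Numerical choices and conventions

- **Percentiles** (quintile cuts and trimming) use the weighted
  lower-interpolation (inverse-CDF) definition; quintile boundary values
  go to the lower group. Any consistent convention is defensible; this
  one is fixed and tested.
- **Quintile cuts** use the baseline weights by default, consistent with
  the weighting of the nonresponse analysis itself; unweighted cuts are a
  configuration toggle.
- **Reference levels** default to the first declared level of each
  covariate (the odds-ratio-1.00 convention), overridable per covariate.
- **Exit-point ties** in the ranking break by the larger maximum
  absolute coefficient at the CV-optimal penalty, then declaration order.
- **Trimming is winsorization**, not deletion: capping preserves the
  respondent count, which deletion would not.
- **Degenerate covariates** (a single observed level) are excluded from
  the design with a logged warning rather than failing the pipeline; an
  empty final LASSO selection falls back to an intercept-only model with
  a prominent warning (every respondent then gets the same weight).
- **Quasi-separation** in the unpenalized AUC-stage fits falls back to a
  weak ridge (1e-3), logged.
- **Variance ratios** use the with-replacement linearization
  Σw²(x−x̄_w)²/(Σw)² against s²/n by default; a subject-level bootstrap
  is available behind `variance_method="bootstrap"` as a cross-check.
- The population (divide-by-n) variance convention is used for s_w^2 so
  the efficiency/inflation identity is exact, not approximate.

## Open design points, and how they were settled

- The ΔAUC significance test is not uniquely determined by the phrase
  "bootstrap": the package uses a paired subject-level bootstrap of the
  AUC difference with fixed in-sample scores (p = share of draws with
  ΔAUC ≤ 0). It is distribution-free and cheap; its known bias — scores
  are not refit per draw — is conservative for small true gains.
- "Three top-ranked per theme vs. three overall" as the starting model:
  per merged theme is the default; `growth="global"` plus `start_k`
  covers the other reading.
- In-sample AUC of a post-selection model is optimistically biased
  (selecting the best-looking of many noise covariates inflates AUC to
  ~0.53–0.55 at n = 4000 even under a null mechanism). The trajectory
  reports the in-sample value because that is what the stopping rule
  compares; genuinely null discrimination is verified in the validation
  suite on independent cohorts, where the stopped models score ~0.50.
- Whether reported CIs should come from the penalized fit or a relaxed
  refit: the refit is used, because penalized Wald intervals are not
  meaningful; this is a reporting interpretation, stated as such.

## Problem sizes used in validation

The validation suite runs 50-replicate simulation studies at the
scenario sizes the procedure is meant for (n = 4000 screening
benchmarks, n = 4500 realism-preset cohorts, a single n = 10,000 cohort
for odds-ratio recovery); unit tests use smaller cohorts (200–2,000
subjects) chosen so each property is decidable well inside Monte-Carlo
error.

## Known limitations

- The procedure uses covariates from a single previous measurement
  point; multi-wave patterns with non-monotone missingness call for
  multiple imputation instead of missing categories, which is out of
  scope here.
- Final weights are computed for the whole respondent sample; analyses
  of subsamples would strictly need re-standardized (or re-estimated)
  weights, which the package does not automate.
- The bootstrap ΔAUC test controls greed, not family-wise error; the
  selected predictor count should be read as a practical stopping point,
  not an inferential statement.
- No design-effect-adjusted inference and no doubly-robust or stabilized
  weighting variants are provided; the estimator is plain 1/PRED.
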