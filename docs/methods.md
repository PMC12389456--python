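# Methods

This note documents the statistical model behind each stage of the
package, the defaults and why they were chosen, and what the synthetic
validation does and does not establish.

## Score construction

**Taxonomy.** The packaged taxonomy (`hpds/data/food_groups.yaml`) maps
24 h recall instrument items to 22 signed food groups with serve sizes
in grams (drinks in mL are counted 1:1 as grams, following the recall
instrument's serve conventions). Alcoholic beverages, highly processed
vegetarian alternatives, vegetable fats and salted nuts are excluded
from scoring by an explicit ignore list — the health evidence for these
categories is heterogeneous enough that assigning them a single sign
would be arbitrary. Two groups (nuts and seeds; legumes and vegetarian
protein alternatives) declare more instrument items than the published
item list names; the fixture stores both the names and the declared
count, and validation surfaces the mismatch as a warning rather than an
error, since the abbreviation is in the source material, not the data.

**Aggregation.** A 24 h amount contributes amount × 7 to grams/week.
With the default `earliest` recall policy only each participant's first
occasion is used (maximizing follow-up time from the baseline
assessment); `mean-of-first-k` averages per-group weekly amounts over up
to k occasions. Multi-recall scoring defaults to score-then-average
(each occasion ranked against its own cohort distribution, then
per-participant totals averaged); averaging intakes before scoring is
available through the `mean-of-first-k` policy. Output rows are sorted
by participant so aggregation is invariant to recall row order.

**Quintile ranking.** Cutpoints are the empirical 20/40/60/80th
percentiles under the linear-interpolation definition (quintile
membership is sensitive to the percentile convention, so it is fixed and
documented). The rank is the count of cutpoints strictly below the
intake: ties at a cutpoint fall into the lower quintile, and collapsed
cutpoints (typical when more than 20% of the cohort reports zero intake)
merge the lowest quintiles, so all zero consumers of a protective group
receive the lowest rank. This is deterministic and conservative for
non-consumers.

**Conventions.** The default subscore is direction × (rank − 2),
summing to an integer in [−44, 44]: centered scoring gives an
interpretable zero (indifferent diet) and symmetric bounds. An
hPDI-style 1–5 convention with reverse coding for discouraged groups
(`convention="quintile15"`) is provided for comparability with the
plant-based-diet-index literature. Published cohort applications of this
index family report non-integer score ranges, implying additional
weighting or averaging steps that are not derivable from the published
description; this package makes no attempt to guess them, and its score
distribution is not expected to reproduce any particular published one.
No energy adjustment is applied before ranking.

**Quartiles and reliability.** Score quartiles use the cohort
25/50/75th percentiles, ties to the lower category; a fully degenerate
distribution logs a warning and assigns Q1. Reliability of single-recall
scoring is the Pearson correlation (t-transform p) between the baseline
(occasion-1) score and the average over all occasions.

## Synthetic cohorts

The generator produces the structure the analysis assumes, not a
calibrated replica of any real cohort.

- **Latent factor.** Each participant has h ~ N(0, 1), "healthy
  eating". Group intake is zero-inflated log-normal: log median weekly
  grams per group (defaults chosen to match the magnitude ordering of
  published quartile tables: staples in the hundreds of g/week, rare
  groups heavily zero-inflated) plus 0.5 · h · direction, log-scale
  person SD 0.8; the zero-intake probability is logistic in h,
  sign-aligned, slope 0.8.
- **Occasions.** The zero indicator compares a person-level uniform
  against an occasion-level logistic propensity; occasion noise
  (`recall_noise_sd`) perturbs both the log amount and the propensity
  logit. At zero noise all occasions are identical (reliability r = 1
  exactly); increasing noise degrades both how much and whether a food
  is captured in a single 24 h window, which is what lets bisection
  reach the moderate-reliability regime (r ≈ 0.53) observed for real
  repeat recalls. One representative item per group is emitted by
  default (multi-item mode splits group mass by symmetric Dirichlet
  weights).
- **Covariates.** Sex, ethnicity, deprivation, income, education,
  supplement use, disease history, activity, sitting, sleep, smoking,
  alcohol, drawn independently of h with a mix resembling a middle-aged
  volunteer cohort (43% male, 96% white, TDI ≈ N(−1.6, 2.9²)). Because
  they are independent of h, sociodemographic score gradients are *not*
  emulated — only the intake gradients needed for construct-validity
  checks.
- **Outcomes.** Event ages follow Weibull proportional hazards on the
  age scale, H(t) = (t/scale)^shape with shape 5 (risk rising steeply
  with age), linear predictor log_hr_per_sd · h plus declared covariate
  effects (male +0.30, current smoking +0.40, TDI +0.03 per unit on the
  log hazard). Entry ages are uniform on 40–69; events are drawn
  conditionally on being event-free at entry via the inverse cumulative
  hazard, so no pre-entry events are ever emitted; administrative
  censoring at entry + 12.3 years (the published median follow-up).
  Baseline scales (102 for incidence, 178 for mortality) were set so the
  marginal event fractions under the default covariate mix land near 10%
  and 0.6%, the published orders of magnitude. Other-cause exits are
  independent censoring: the models are cause-specific hazards, and no
  competing-risk structure is simulated.

All randomness flows from one integer seed; identical configs give
byte-identical outputs.

## Survival analysis

Cox partial-likelihood fits use lifelines (`entry_col` left truncation)
with Efron ties — age-scale data are tie-heavy in real applications —
and a statsmodels PHReg backend for Breslow ties; on tie-free data the
two agree and serve as mutual cross-checks. Exposures: score quartiles
(Q1 reference; a quartile with zero events is flagged non-estimable and
reported as NaN rather than a divergent coefficient), the continuous
score standardized per SD (the trend test is the Wald p on this
coefficient in the otherwise identical model), or a single food group's
grams/week per SD (22 such models share one covariate set).

**Proportionality.** Residual-based diagnostics for left-truncated fits
are not available in the fitting backend, so the Grambsch–Therneau
Schoenfeld-residual score test is implemented directly: at each event
age the residual is the event's covariate vector minus the risk-weighted
mean over the risk set {entry < t ≤ exit} (risk sets honor delayed
entry; suffix-sum accumulation keeps this O((n + d)·p²)); the
correlation of residuals with the rank transform of event age gives
per-term χ²(1) statistics and a global χ²(p), verified to reproduce the
reference implementation exactly on non-truncated data. Covariates
rejecting at p < 0.05 are moved from the linear predictor to strata
(continuous covariates are binned into quartiles first, since stratified
partial likelihood needs discrete strata) and the model is refit; the
decision is logged.

**Interactions and multiplicity.** Effect modification is tested with a
product term between the standardized score and the modifier (centered);
subgroup fits split by sex level or at the modifier's cohort median.
p-values are BH-adjusted; the default family is all outcome models in
one analysis run, with a per-outcome family selectable — family
membership is recorded in the output. Missing covariates are handled as
complete cases with a logged count; multiple imputation is out of scope
(synthetic data are complete, and imputation is standard external
tooling). A sensitivity filter excluding self-reported diagnoses is
represented as a boolean source flag on the outcome table.

## Reporting

Quartile characteristic tables report mean (SD with n−1 denominator)
and N [%]. Headline Q4−Q1 contrasts are rounded decimal-half-up at a
declared precision (integer, nearest-10, or one decimal) with the exact
difference always retained, because published contrasts are often
loosely rounded and both values must stay visible. Incidence
proportions use the same half-up rule. Forest tables prepend a Q1
reference row with HR 1.00.

## Validation experiments and their problem sizes

The test suite and `scripts/acceptance.py` run: brute-force scorer
equivalence on 100 random cohorts of n ≤ 100; score bound/decomposition
fuzzing; hazard-ratio recovery (true HR 0.8 per SD) and 95% CI coverage
at n = 10,000 over 50 seeds; trend-test null calibration at n = 2000
over 100 seeds; exhaustive Benjamini–Hochberg verification for all
vector lengths m ≤ 8; and bisection of the recall-noise SD to the
r ≈ 0.53 reliability design point at n = 2000 with 5 recalls. These
sizes give comfortably stable Monte-Carlo checks (e.g. coverage
granularity 2% at 50 seeds) at desk-scale runtimes.

## Limitations

Passing these checks shows the pipeline is internally correct and well
calibrated under its own generative assumptions. It does not show that
the simulator matches any real cohort's joint distributions: covariates
are independent of diet, competing risks are absent, intakes are
log-normal, and published hazard-ratio estimates from restricted cohort
data are not reproducible here. The exact arithmetic behind published
non-integer score ranges is unavailable, so cross-study score
comparisons should use the conventions documented above.
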