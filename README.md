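# hpds — heart-protective diet score and survival analysis pipeline

`hpds` implements a 22-food-group diet-quality index for cardiovascular
epidemiology — a signed, cohort-relative quintile-rank score over 24 h
dietary recall data — together with everything needed to validate it and
estimate its association with disease: recall-to-food-group aggregation,
scoring, a synthetic cohort generator, cause-specific Cox proportional-
hazards models with age as the timescale, and quartile-table reporting.

It is aimed at nutritional epidemiologists who want a reproducible,
testable implementation of the quintile-rank diet-index family (PDI /
hPDI / uPDI and relatives) extended to animal-source foods, and at
methodologists who want a fully simulated test bed for left-truncated
survival pipelines.

## The score

Food and drink items from a 24 h recall instrument are mapped to 22 food
groups, 11 heart-protective (wholegrains, fruits, non-starchy and starchy
vegetables, nuts and seeds, legumes, uncoated fish, eggs, reduced-fat
dairy, tea/coffee, homemade soup) and 11 discouraged (refined grains,
potatoes, meat and processed meat, coated fish, full-fat dairy, processed
soup, sweets, savory snacks, sugary drinks, artificial sweetener,
spreading fats). For participant *i* and group *g* with direction
*d_g ∈ {+1, −1}*:

- intake *x_ig* (grams/week) is ranked against the cohort's empirical
  20/40/60/80th percentile cutpoints for that group, giving a quintile
  rank *r_ig ∈ {0, …, 4}* (ties at a cutpoint fall into the lower
  quintile, so zero consumers of a zero-inflated group share the lowest
  rank);
- the group subscore is *d_g (r_ig − 2) ∈ [−2, 2]*;
- the total score is HPDS_i = Σ_g *d_g (r_ig − 2)*, an integer in
  [−44, 44] (an hPDI-style 1–5 reverse-coded convention is also
  available).

Cohort score quartiles Q1 (lowest adherence, reference) to Q4 feed the
association models: Cox proportional hazards with attained age as
analysis time, left truncation at recruitment age, Efron ties
(Breslow selectable), Schoenfeld-residual proportionality checks with
automatic stratification fallback, linear-trend and interaction tests,
and Benjamini–Hochberg FDR across the model family.

Because real cohorts of this kind are access-restricted, the package
ships a synthetic cohort generator (zero-inflated log-normal group
intakes tied to a latent healthy-eating factor, repeat recalls with
intra-individual noise, Weibull proportional-hazards outcomes on the age
scale) so the whole pipeline is exercised and validated end to end.

## Worked example

```
hpds run --out-dir demo --seed 1 --n 2000
hpds report --results demo/results.csv --out demo/report.txt
```

simulates a 2000-person cohort, aggregates the recalls, scores the
cohort, fits the Cox models, and prints:

```
== cvd (n=1969, events=195) ==
  Q1    1.00 (reference)
  Q2    1.08 [0.73, 1.59]  p=0.71  p_adj=0.824
  Q3    0.95 [0.64, 1.43]  p=0.824  p_adj=0.824
  Q4    0.80 [0.52, 1.22]  p=0.306  p_adj=0.824
  trend p = 0.258
```

Reading this: after excluding the 31 participants prevalent at baseline,
195 of 1969 participants had an incident event; the fitted hazard ratio
for the top versus bottom score quartile is 0.80 (the generator's
default protective effect is log-HR −0.1 per SD of the latent factor),
with a wide interval because 2000 participants yield few events —
the parameter-recovery experiments in `scripts/acceptance.py` use
n = 10,000, where the estimate is sharp. All artifacts (scores,
per-model results, forest rows) are CSVs under `demo/`, and
`manifest.json` records a content hash per artifact: rerunning with the
same seed reproduces the hashes exactly.

The same stages are importable as a library — `aggregate_group_intake`,
`HeartProtectiveDietScorer` (an sklearn-style transformer: `fit` learns
the cohort cutpoints, `transform` emits subscores), `CoxSurvivalModel`,
`quartile_characteristics`, and friends.

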