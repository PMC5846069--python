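# Methods

This note documents the statistical procedures implemented in `crc_riskval`,
the assumptions behind them, the defaults of the synthetic cohort generator,
and the design choices made where the design was genuinely open.

## Scoring published risk models

A risk model is a `ModelSpec`: covariate definitions, weighted terms, and
the baseline quantities demanded by its functional form. The linear
predictor is the plain weighted sum `Σ βᵢ·tᵢ(xᵢ)`, where each term's value
is a level indicator (categorical), a 0/1 presence flag (binary), or a
continuous value passed through a transform chain (`identity`, `log`,
`center(offset)`, `scale(divisor)`, `indicator(level)`, composed in listed
order). Absolute risk over the model's native horizon follows from the
form:

| form | risk |
|---|---|
| logistic | expit(intercept + lp) |
| cox | 1 − S₀^exp(lp − mean_lp) |
| points | non-decreasing step lookup of the integer point total |
| rr_product | min(1, baseline_risk · exp(lp)), coefficients on the log-RR scale |

Two deliberate choices here. First, relative-risk-product scores are made
total and testable by pairing the RR product with a *configurable* baseline
absolute risk capped at 1 — the population-average baselines for such
consensus scores are frequently unpublished, so the baseline is an input,
not an assertion. Second, sex applicability is an advisory flag rather than
a hard filter: validation studies routinely score male-derived models on
women, and the pipeline reports the applicable fraction instead of refusing
to score. Age-range applicability (e.g. a model defined only for ages
50–89) is enforced when risk is requested for a single record and reported
as a flag in batch scoring.

Scalar and vectorised scoring paths are implemented separately and held
equal by tests; dropping a term is exact (`drop_terms` rebuilds the spec, so
additivity of the linear predictor is a structural identity, not a numeric
approximation).

## Cohort definition and missing data

The closed validation cohort removes participants with a prior CRC
diagnosis (ICD-9 153.x/154.0/154.1/154.8, ICD-10 C18.x/C19/C20/C21.8, exact
code membership), removes records with a death date before baseline, and
requires five years of potential follow-up — *except* when follow-up ended
in death, which is retained to reflect how a risk score would be applied in
practice. The per-step counts are recorded as provenance so the cohort-flow
arithmetic is machine-checkable. The retained set is invariant to the order
of the three predicates.

The primary analysis is complete-case **per model**: a participant enters a
model's validation sample iff every covariate that model references is
observed, so the analysed n legitimately differs between models. The
extreme-case analysis brackets the impact of missingness: for any factor
with more than 5% missing, continuous values are imputed to the observed
90th or 10th nearest-rank percentile and dichotomous values to present or
absent. The direction (high/low) is a parameter and the battery reports
both directions, because a per-factor direction rule would be a guess;
multi-level categorical factors are left untouched (only continuous and
dichotomous factors have a defined "extreme"). Nearest-rank percentiles
were chosen over interpolation so the imputed value always equals an
observed one and matches a sort-based oracle exactly.

## Horizon conversion

Risks stated over 10 or 20 years are compared at 5 years on the
cumulative-hazard scale H = −log(1−p):

- **constant hazard**: H(t) ∝ t, so H₅ = H₁₀/2 = H₂₀/4;
- **doubling hazard**: the hazard doubles every d years (default d = 5),
  H(t) ∝ 2^(t/d) − 1, giving H₅ = H₁₀/3 = H₂₀/15. Non-integer block counts
  are covered smoothly by the same formula, and hazard fractions of the
  fixed growth curve compose multiplicatively (20→10→5 equals 20→5 exactly).

Working on the hazard scale keeps converted risks in [0, 1) for every
input and agrees with naive probability scaling (p₅ = p₁₀/2 or p₁₀/3) to
first order — relative error under 1% for p < 0.01, the magnitude of 5-year
CRC risks. Because published analyses rarely state which arithmetic they
used, probability-scale conversion is available behind `scale="probability"`;
neither is claimed to be anyone's exact arithmetic. p = 1 is rejected
(infinite hazard).

## Discrimination and calibration

**AUC** is the Mann–Whitney concordance probability computed from midranks,
so ties contribute ½ exactly. The confidence interval uses the DeLong
placement-value variance (the standard for validation studies); the
implementation reproduces an independent DeLong implementation (R `pROC`)
to 10 decimals on a fixed dataset, and equals brute-force pairwise
concordance on every tested input. Hanley–McNeil is available as a
small-sample fallback. Perfect separation yields a degenerate interval.

**Harrell's C** handles the open-cohort design: a pair is comparable when
the shorter observed time is an event (an event and a censoring at the same
time are ordered event-first, matching the convention in `lifelines`,
against which the implementation is cross-checked); score ties count ½.
The implementation is exhaustive-pair enumeration, vectorised in chunks —
O(n·events) memory-bounded, adequate for the cohort sizes used here.

**Threshold metrics** flag the top fraction q of the population. With
discrete scores (point models) many records tie at the cutoff; ties are
broken in stable participant order so that exactly round(q·n) records are
flagged, honouring the "top 10% of the population" definition rather than
the cutoff value. Sensitivity, specificity, LR± and predictive values
follow from the confusion matrix; `metrics_from_rates` inverts the same
identities to rebuild the full metric set from a published
sensitivity/specificity/n/events quadruple, which is how printed validation
tables can be checked for internal consistency.

**Calibration** groups participants into equal-count deciles of predicted
5-year risk (tied predictions kept together; a constant prediction vector
degenerates to one group and is rejected if its mean is 0 or 1). The
Hosmer–Lemeshow statistic is Σ (O−E)²/(E(1−p̄)) with E = n·p̄ per group.
Degrees of freedom equal the number of groups: in external validation no
parameter was estimated on these data, so the development-setting g−2
convention does not apply. This choice is documented rather than attributed
— published validation studies rarely state their df.

Outcomes are binary at five years in the closed cohort; deaths within five
years without CRC count as non-events. The `colon` outcome scope restricts
events to the colon subtype for models developed against colon rather than
colorectal cancer.

## Synthetic cohort generator

The generator emulates the marginal structure of a UK-Biobank-scale
validation population; defaults (all configurable):

| quantity | default | note |
|---|---|---|
| age | truncated normal(56.4, 8.1) on [40, 70] years | recruitment window; effective SD 6.83 |
| sex | 45.5% male | |
| family history of CRC | 10.8% | |
| smoking never/former/current | 54.6/34.6/10.8% | renormalised marginals |
| BMI category <20/20–25/25–30/≥30 | 2.3/30.8/42.5/24.4% | |
| physical activity | normal(28.3, 5.5) MET-h/day | |
| red meat ≥3×/week | 22.3% | |
| alcohol non/former/current | 4.2/3.7/92.1% | |
| aspirin / NSAID use | 15.1% / 31.5% | |
| 5-year incidence target | 0.46% | |
| missingness | e.g. physical activity 11.7%, family history 4% | MCAR per factor |
| prior conditions | prior CRC 0.46%, polyp 3%, IBD 0.7% | ICD-coded |

Factors are sampled independently except for declared **age tilts**
(logistic shifts of a factor's log-odds per SD of age; defaults: current
smoking −0.25, NSAID +0.30, aspirin +0.55 per SD), because only marginals
are published and medication for pain relief is known to rise with age —
which is exactly the confounding pattern that makes aspirin/NSAID terms
behave counterintuitively in validation. Joint structure beyond these tilts
(e.g. BMI–activity correlation, assessment-centre geography, the healthy-
volunteer selection of a real volunteer cohort) is *not* modelled, so
passing tests demonstrate correctness of the machinery under the stated
marginals, not fidelity to any real population's joint distribution.

Outcomes: the default generative truth is a synthetic logistic 5-year model
(age 0.088/yr centred at 56.4, male 0.35, family history 0.35, smoking
former 0.30 / current 0.15, BMI 0.12/0.22, red meat 0.15 on the log-odds
scale). The age coefficient was set analytically so the linear predictor's
SD is ≈0.66 given the truncated-age SD of 6.83, which for a rare outcome
gives AUC ≈ 0.67 — the discrimination regime of the better published CRC
models. Raw risks are rescaled by a single multiplicative constant so the
expected incidence matches the target (transparent and invertible; an
intercept shift would be form-dependent); the run fails if rescaling would
push any risk above 1. Events are Bernoulli draws against the true risk
with event times uniform on (0, 5], matching a constant event incidence
over follow-up (no within-follow-up ageing). A configurable fraction of
non-events is censored before five years (`admin`), and a small fraction
(default 0.5%) dies within five years (`death`) so the deaths-retained
closed-cohort rule has positive test cases. Event subtypes are colon with
probability 0.72, rectal otherwise (approximate anatomical split of
colorectal registrations). The truth table (true risk, latent draw,
uncensored event time) is returned solely as a test oracle.

Determinism: one `numpy` Generator seeded from the config; identical config
and seed yield byte-identical cohorts.

## Numerical and reporting conventions

- All computation at full precision; reports round half-even to 1 decimal
  for percentage metrics and 2 for AUC and likelihood ratios, with raw
  values preserved in JSON.
- Quantile cutoffs use the empirical (1−q) quantile; flagged counts are
  exact by construction (see tie policy above).
- Reports are byte-deterministic given a configuration (sorted keys, stable
  ordering), and invariant to the order in which model files are listed.
- The per-stratum problem sizes used by the shipped experiments: 373 000
  participants for the headline threshold-metric run, 200 000 for
  model-ranking recovery (5 seeds), 20 000 × 50 seeds for the
  Hosmer–Lemeshow recovery check, 150 000 for the horizon-mismatch
  demonstration. These sizes put binomial noise well below the effects
  being demonstrated at ~0.5% incidence.

## Known limitations

- ICD matching is exact membership, not prefix/range expansion; code sets
  must enumerate the codes they intend.
- The RR-product engine treats coefficients as log-RRs with a user-supplied
  baseline; validating a published consensus score therefore validates its
  ranking, not its absolute calibration, unless the true baseline is known.
- Harrell's C is O(n·events) time; for cohorts beyond a few hundred
  thousand with high event counts a rank-tree implementation would be
  preferable.
- The generator produces harmonized covariates directly; raw-field
  derivation rules are exercised on hand-built fixtures rather than on
  generator output.
- No competing-risk adjustment and no age-conditional residual-lifetime
  risks; the horizon converter treats risk as a single-cause quantity.
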