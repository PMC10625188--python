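# Methods

This note documents the models, parameter choices and numerical conventions
of `ecanon`, and what the synthetic experiment does and does not show about
real registry data.

## Synthetic cohorts

The generator emulates two arms of an elderly atrial-fibrillation (AF)
population exposed to non-vitamin-K oral anticoagulants (NOACs): a
registry-like real-world arm (`RWD`, default n = 3,327) carrying an
overall-survival outcome, and a trial-control-like arm (`RCT`, default
n = 250) carrying baseline data only. The 36 baseline confounders are age
(truncated normal on [45, 105], stored as whole years), sex, 33 binary
comorbidity/medication flags and a three-category time-since-AF-diagnosis
variable; each arm targets its own published marginal column. Summary
cells reported only as "< 5" in the source tables are encoded with small
synthetic stand-in counts (3/3,327 and 2/250).

**Copula.** Values are drawn by thresholding a latent Gaussian vector, so
every marginal is met in expectation regardless of correlation. The source
populations publish no correlation structure; the default is exchangeable
latent correlation 0.15 among the comorbidity flags and 0.25 between age and
each flag (sex and the categorical variable independent), configurable and
validated for positive semidefiniteness.

**Outcome.** Overall survival follows a Weibull proportional-hazards model
with baseline cumulative hazard H0(t) = (t/scale)^shape, shape 1.2 and scale
5,700 days, chosen to give roughly 7%/year mortality — realistic for a
76-year-old AF cohort — i.e. ~25–30% deaths over the follow-up. Event times
are drawn by inversion, rounded up to whole days, and administratively
censored at the study-end date 2020-12-31; death dates beyond that date are
not recorded, as a registry would not know them at data lock. Default
log-hazard ratios are nonzero for ten clinically plausible covariates
(age 0.055/year; heart failure 0.5; malignancy 0.6; kidney disease and COPD
0.4; myocardial infarction and anemia 0.3; stroke 0.25; diabetes and male
sex 0.2), all within a moderate ±0.7 band; continuous covariates are
centred at their target mean in the linear predictor.

**Entry.** First NOAC dates are uniform over the accrual window
(2014-01-01 to 2019-09-30). The study entry (index) date is the first NOAC
date for naïve subjects; a seeded simple random sample of round(0.584 · n)
subjects — matching the trial arm's share of prior NOAC users — becomes
"artificial current users" whose entry is shifted by a treatment duration
drawn from the trial's on-treatment time distribution (modelled as
exponential with mean 180 days, since subject-level durations are not
public), truncated to keep entry at least one day before study end.
Subjects dead before their artificial index date are dropped and logged
(immortal-time avoidance). A covariate-dependent selection rule was
deliberately avoided: it would inject confounding the experiment is not
meant to contain.

What the generator does **not** emulate: diagnosis-code streams,
prescription event histories, registry linkage errors, missingness,
measurement drift, or informative censoring. Passing tests therefore
certify the pipeline's statistical machinery under a clean data-generating
process, not the data quality of any real registry.

## (k, ε)-anonymization

The privacy model combines k-anonymity (default k = 5) on the
quasi-identifiers with per-variable ε-differential privacy (default
ε = ln 32 ≈ 3.466) on released values. The budget is **per attribute**, not
per record: no composition across variables is accounted. This mirrors a
single-ε-per-variable production setting and is stated loudly because it is
strictly weaker than whole-record ε-DP.

* Quasi-identifiers: age and sex. Age is banded only for equivalence-class
  formation; the released age is the noised value. The default band width
  is 10 years: with the default cohort size the tail age × sex classes then
  stay above k, so k-repair activates only on unusual draws rather than on
  every run (5-year bands would make the extreme-age classes structurally
  too small at n ≈ 3,300).
* Numeric variables: Laplace(0, Δ/ε) noise. Δ defaults to the variable's
  domain width (worst case); the default schema sets Δ = 10 years for age,
  a calibration that adds noise of SD ≈ 4 years — the anonymized-age
  dispersion observed in practice — since production sensitivities are not
  published. Survival time, when anonymized, uses Δ = 30 days.
* Categorical variables: the exponential mechanism with identity utility,
  i.e. randomized response — keep with probability e^ε/(e^ε + m − 1), else
  uniform among the other m − 1 levels; its worst-case probability ratio is
  exactly e^ε. A config switch restricts categorical noising to the records
  that failed the k-criterion instead of all records (default: all).
* k-repair: records in classes smaller than k have their quasi values
  re-drawn through the same mechanism for up to `max_repair_rounds` rounds;
  residual violators are deterministically folded into the largest
  compliant class. Because noising age and sex can re-break classes, a
  **final repair pass runs after cleaning**, so every released table
  satisfies the k-criterion by construction (checked and asserted on
  release).
* Cleaning clamps noised numerics into their domains and rounds
  integer-valued variables; direct identifiers and exact dates are
  suppressed (columns kept, values blanked); rows are shuffled and given
  fresh random record identifiers. The record count is always preserved.
* An `anonymize_outcomes` switch excludes the survival columns from
  noising, supporting the sensitivity analysis in which only baseline
  covariates are perturbed.

**Risk bound.** The maximum membership-disclosure probability is taken as
ρ(ε, n) = 1 / (1 + (n − 1) e^(−ε)): a uniform-prior adversary's posterior
of identifying one member of an n-cohort after an ε-DP release. At
n = 8,255 it gives 0.39% for ε = ln 32 and 0.012% for ε = 0.01 — the two
anchor values the formula was validated against. At ε = 7 it yields 11.73%
where 11.77% has been reported elsewhere; the small residual (rounding or a
variant form of the bound) is documented rather than patched.

## Privacy audit

The membership-inference attack is the standard nearest-neighbor baseline:
each probe is scored by the negative distance to its closest released
record (squared standardized Euclidean over continuous covariates plus a
Hamming count over categorical ones), and member vs non-member scores are
ranked into an ROC AUC (midrank tie convention), repeated over resampled
probe sets. The attack object is pluggable; shadow-model and
attribute-inference attacks are out of scope. The analytic ρ bounds a
different quantity (worst-case disclosure probability) than the attack
advantage; the audit table flags advantage > ρ as a diagnostic, not a
violation.

## Balancing

The propensity model is maximum-likelihood logistic regression on all 36
confounders (categorical variables expanded to non-reference indicators).
statsmodels provides the initial fit; a damped Newton polish with
pseudo-inverse steps then drives the score to max |g| < 1e−10, which makes
the overlap-weighting exact-balance identity hold to ~1e−12 even when a
rare flag has an empty arm × level cell (quasi-separation — routine with a
250-subject trial arm; it is warned about and tolerated, while a covariate
that predicts the arm perfectly raises an error naming it).

Matching is greedy 1:1 nearest-neighbor without replacement on the logit
propensity, trial subjects processed in seeded random order, accepting
pairs within a caliper of 0.2 × the pooled SD of the logit (the cited
convention for "width 0.2"; a raw-logit-width mode is available). Distance
ties break to the lowest control row position. Greedy matching optimizes no
global objective; the test suite verifies it against an exhaustive
enumeration of the greedy rule over all processing orders on small
instances where that rule is order-invariant.

Matching weights are min(e, 1−e)/P(own arm); overlap weights are 1−e
(trial) and e (control). Balance is the absolute standardized mean
difference — binary: |p₁−p₂| / √((p₁(1−p₁)+p₂(1−p₂))/2); continuous:
|m₁−m₂| / √((s₁²+s₂²)/2) — with weighted means but **unweighted** arm
variances in the denominator, so a weighting scheme cannot flatter its own
diagnostic. Labels: success < 0.1, moderate 0.1–0.25, fail above. Effective
sample sizes are Kish (Σw)²/Σw² per arm.

## Outcomes

Kaplan–Meier estimation (optionally weighted) uses lifelines, with
Greenwood standard errors computed from the event table and log(−log)
95% bands. Cox models use lifelines' Efron tie handling with Wald CIs;
monotone-likelihood cases are returned as non-converged with a
diverging-HR diagnostic instead of raising. The anonymization contrast
stacks the two versions of the same cohort with a dataset indicator and
reports the indicator's HR; the two copies of each subject are treated as
independent samples (plain variance), matching how such contrasts are
usually reported, with a robust-variance option off by default. For the
matched subset, matching is re-run per data version, so the contrast
includes the selection effect of matching on noised covariates.

## Pipeline and reproducibility

Per-stage seeds derive from blake2s(master seed, stage name) mod 2³¹, so
adding a stage never shifts another stage's stream; the matching stage
shares one seed across the pseudonymized and anonymized branches, making
the two branches identical in the no-noise limit (ε → ∞, outcome
anonymization off) up to floating-point tie degeneracies in greedy
matching. Small-cell "< 5" masking applies only to rendered text, never to
stored CSVs. Reports are byte-reproducible under a fixed config.

Default problem sizes used throughout the tests are the study-scale ones
(3,327 + 250); heavy simulation checks use 50 replicates (survival CI
coverage at n = 5,000/arm), 20 seeds × 1,000 rows (k-anonymity), 10 seeds
(balance success), and 500 random instances (matcher oracle) — sizes chosen
to keep Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Per-attribute ε-DP without composition accounting; no multi-release
  accounting and no ε-safe-k-anonymization variant.
* The nearest-neighbor attack is a lower bound on adversarial capability.
* Greedy matching is order-dependent on tied/near-tied instances.
* The pseudo-vs-anon Cox contrast ignores the pairing of duplicated
  subjects unless the robust option is enabled.
* Synthetic marginals reproduce published summary columns, not subject-level
  reality; correlations and the outcome model are package defaults, not
  estimates.
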