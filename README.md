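# ecanon

**External control arms from anonymized real-world data.**

Single-arm trials increasingly borrow their comparator from registry data
("external control arms", ECAs). In the Nordic countries, subject-level
registry data usually may not leave the secure analysis environment unless
it is *anonymized* — transformed so that re-identification is practically
impossible — which inevitably distorts the data the ECA is built from.
`ecanon` implements that whole experiment as a reproducible pipeline on
synthetic data, for biostatisticians and privacy engineers who want to
quantify the trade-off:

1. **Synthetic cohorts** — a registry-like arm (default n = 3,327, with
   overall survival) and a trial-control-like arm (default n = 250, baseline
   only) for an elderly atrial-fibrillation population starting oral
   anticoagulation, with 36 baseline confounders drawn through a Gaussian
   copula and a Weibull proportional-hazards outcome.
2. **(k, ε)-anonymization** — k-anonymity (k = 5) on quasi-identifier
   equivalence classes plus per-variable ε-differential privacy
   (ε = ln 32): Laplace noise on numeric variables, a randomized-response
   exponential mechanism on categorical ones, cleaning, shuffling and random
   re-identification, preserving the record count.
3. **Balancing** — a 36-covariate logistic propensity model e(x) = P(trial
   arm | x); greedy 1:1 caliper matching on logit e (caliper 0.2 × SD),
   matching weights min(e, 1−e)/P(own arm) and overlap weights
   (1−e / e), with balance reported as standardized mean differences
   (success < 0.1).
4. **Outcomes** — Kaplan–Meier curves and a Cox model of the
   anonymized-vs-pseudonymized contrast: the hazard ratio of a dataset
   indicator over the stacked pair of data versions, overall and within the
   matched subsets.
5. **Privacy audit** — the closed-form maximum membership-disclosure risk
   ρ(ε, n) = 1 / (1 + (n − 1) e^(−ε)) next to an empirical nearest-neighbor
   membership-inference attack (reported as ROC AUC) over an ε grid.

## Worked example

```bash
ecanon run-all --seed 42 --out demo/
```

prints

```
matched counts: pseudo=236, anon=245
anonymization HR [all]: 1.045 (0.956-1.142, p=0.329)
anonymization HR [matched]: 0.950 (0.692-1.303, p=0.748)
anonymization HR [unmatched]: 1.053 (0.960-1.156, p=0.271)
report written to demo/
```

Reading: both the pseudonymized and the anonymized version of the synthetic
registry arm produced a matched external control arm of roughly the same
size (236 vs 245 of 250 trial subjects matched). Anonymization shifted the
overall-survival hazard by about 4.5% before matching and by about 5% in the
matched subset — in both cases the 95% confidence interval covers 1, i.e.
the distortion is statistically indistinguishable from none at this sample
size, while individual-record privacy is protected at ρ < 1%.

The output directory holds the full report: baseline descriptive tables for
the pseudonymized / anonymized / trial arms, pre- and post-balancing SMD
tables for each method and data version, matched-pair lists, propensity
scores, Kaplan–Meier curves (CSV + figure), per-covariate Cox forests, the
privacy-audit grid (attack AUC vs analytic ρ per ε) and a manifest with the
config hash and all per-stage seeds. Re-running with the same seed
reproduces every file byte for byte.

The same stages are available individually (`ecanon generate`,
`anonymize`, `balance`, `outcomes`, `audit`) and as library functions
(`ecanon.synth`, `ecanon.anonymize`, `ecanon.balance`, `ecanon.outcomes`,
`ecanon.audit`, `ecanon.pipeline`).

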