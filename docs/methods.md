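# Methods

## The problem

Patients re-irradiated in the thorax (recurrent lung or oesophageal cancer)
accumulate dose to the oesophagus across two radiotherapy courses. High-grade
(CTCAE grade ≥3) oesophageal toxicity — oesophagitis, dysphagia, stenosis,
haemorrhage, perforation, tracheo-oesophageal fistula — is dose-limiting,
and evidence-based *cumulative* dose constraints are scarce because each
retrospective series is small. This package implements the pooled-analysis
machinery that turns a collection of such series into a dose constraint: a
normal-tissue complication probability (NTCP) model of logistic form in
cumulative oesophageal dose and concurrent chemotherapy, inverted to the
dose predicting a chosen toxicity rate.

## Dose scale

All doses are expressed as equivalent dose in 2-Gy fractions:

    EQD2 = D · (d + α/β) / (2 + α/β)

with D the physical total dose and d the dose per fraction. The α/β ratio
is 10 Gy for acute oesophageal effects (events within 3 months of
re-irradiation) and 3 Gy for late effects; for prospective prediction the
late value is the default, so constraints are quoted in Gy₃. Cumulative
dose is the plain sum of per-course EQD2 values — no repopulation or
inter-course recovery factor is applied; the interval between courses is
instead offered to the regression as a candidate covariate. `Eqd2Dose`
values carry their α/β annotation and refuse arithmetic across ratios, so
Gy₃ and Gy₁₀ quantities cannot be silently mixed.

## Likelihood

Source studies report at two granularities: patient-by-patient doses, or a
grouped summary (n, event count, median cumulative D_max, chemotherapy
rate). Both enter one likelihood: a patient contributes a Bernoulli term at
its own covariates, a grouped study a binomial(n, events) term at its
representative covariates. The linear predictor is

    logit P(≥G3) = β₀ + β_dose·CD + β_chemo·CC

with CD the cumulative oesophageal D_max (Gy EQD2) and CC concurrent
chemotherapy. For grouped studies CC enters as the fractional chemotherapy
rate by default (a dichotomised coding at 0.5 is available; the published
coding is not recoverable from the printed model). The log-likelihood is
the binomial kernel (no binomial coefficients), so a cohort of n identical
patients is exactly equivalent to its n patient records — a tested
invariant.

Fitting is Newton–Raphson with step-halving, convergence at gradient
max-norm < 1e−8, at most 100 iterations, on internally standardized
columns; the covariance is the inverse observed information at the optimum.
Complete separation is detected by coefficient divergence (|β| > 50 on the
original scale) and flagged — never silently returned, and never penalised,
because downstream quantities are plain ML estimates. Missing covariates
are never imputed: units missing any covariate of the current model are
dropped and counted, per model.

## Model building

1. **Median-split tests.** Each candidate predictor (dose, chemotherapy,
   interval) is split at its median and tested against the outcome with a
   chi-squared test (no continuity correction), switching to Fisher's exact
   test when any expected cell count is below 5 (the conventional rule; the
   choice is recorded per test).
2. **Univariable screen.** One univariable logistic fit per candidate;
   candidates with Wald p < 0.2 proceed.
3. **Multivariable fit.** Gated covariates are fitted jointly; covariates
   other than dose that lose significance there (p ≥ 0.05) are dropped.
4. **Leave-one-study-out cross-validation.** Candidate models (dose-only
   vs multivariable) are compared by held-out negative log-likelihood:
   each study in turn is removed, the model refitted, and the held-out
   study scored; fold scores are summed and the lowest total wins. Folds
   that fail for any candidate (non-convergence, or a held-out study with
   no complete-case units) are excluded for all candidates, keeping totals
   comparable.

## Dose constraints and intervals

The fitted model inverts in closed form:

    CD(p, CC) = (logit(p) − β₀ − β_chemo·CC) / β_dose

The chemotherapy shift β_chemo/β_dose is a rate-independent horizontal
offset between the two curves. Two interval methods are provided:

- **Wald (delta method)** on the inverted dose, using the gradient
  (−1, −CD, −CC)/β_dose against the fitted covariance. The published table's
  non-bootstrap interval method is unstated; the delta method is the
  standard inverse-prediction interval and is labelled as such.
- **Study-level block bootstrap**: whole studies are resampled with
  replacement (resample size = number of studies, preserving the
  between-study clustering/overdispersion that motivates blocking), the
  model refitted and re-inverted per replicate, and the 2.5th/97.5th
  percentiles of converged replicates taken. Replicates that separate or
  fail to converge are dropped and counted; more than 50 % failures is a
  hard error. A single seeded generator drives each run and the seed is
  recorded. Interval bounds are deliberately not truncated at zero — a
  strongly left-shifted with-chemotherapy curve legitimately yields a
  negative lower bound.

## Diagnostics

**Decile calibration**: complete-case units are sorted by modelled risk
(stable sort, so tied grouped predictions bin deterministically), cut into
ten equal-count bins (remainder spread over the lowest bins), and the mean
predicted rate per bin is correlated with the observed rate (Pearson; the
p-value is the usual t-test with 8 degrees of freedom).
**Threshold discrimination**: observed toxicity rates strictly above versus
at-or-below a dose cutoff; an empty group reports an undefined rate, never
zero.

## The packaged fixture

`oesotox.data` ships the transcription of a published 21-study pooled
dataset (505 patients, 57 raw events, 49 affected patients after collapsing
the 8 patients with both an acute and a late event). Reconciliation rules
and known transcription discrepancies are documented in
`src/oesotox/data/provenance.md`. Because only study-level summaries are
printed, a pseudo patient-level expansion is provided for patient-level
code paths: every patient sits at the study's median dose, chemotherapy
goes to the first round(n·rate) patients and events to the first `events`
patients (events therefore co-occur with chemotherapy maximally). This is a
flagged reconstruction convention, not data; analyses on it are qualitative
mirrors only. In particular, refitting the model to the study table does
not reproduce the published coefficients — the published fit used
unit-level doses for several studies, which are not printed — so the
packaged constraints derived from the refit are wider and higher than the
published ones, and the published coefficients themselves are carried as
`oesotox.model.published_model()` for exact closed-form work.

## Synthetic cohorts

`oesotox.synthetic` draws multi-study datasets with the structure the
analysis assumes: ~21 studies of 1–60 patients (a preset mirrors the
fixture's exact sizes and chemotherapy rates), per-study log-normal dose
locations (overall median ≈ 85 Gy₃, between-study SD 0.45 and within-study
SD 0.25 on the log scale, truncated to the observed 3.7–220.6 Gy₃ span),
spike-and-uniform per-study chemotherapy policies (half of studies give no
chemotherapy, a fifth give it to everyone, the rest a uniform rate —
echoing the all-or-nothing pattern of the source studies), log-normal
intervals (median 15.5 months, truncated to 1–162), and events drawn from
the logistic model with the published coefficients as the default truth.
Identical (design, seed) pairs give identical datasets. What the generator
does **not** emulate: within-study dose–chemotherapy correlation,
follow-up/censoring structure, volumetric dose metrics, grading-scale
heterogeneity between studies, and publication bias — so passing
recovery/coverage tests demonstrate correctness of the machinery under the
assumed model, not robustness to those real-data features.

## Verification strategy and problem sizes

Quantities that are printed (the eight iso-risk doses, the fixture totals,
the event-category accounting, the chemotherapy shift) are re-derived
exactly. Quantities that depend on the unpublished unit-level dataset (the
fitted coefficients, LOOCV totals, bootstrap bounds, decile r, cutoff
rates) are verified as statistical properties on synthetic data generated
from the published coefficients: coefficient recovery within 3 SE at
n = 10,000 (100 replicates), LOOCV preferring the dose+chemotherapy model
when the chemotherapy effect is real (100 datasets of 21 studies,
~2,000 patients each), and 95 % block-bootstrap coverage of the true 5 %
iso-risk dose (200 outer replications at B = 500, 21 studies of 24
patients ≈ the fixture's 505). The MLE is cross-checked against an
exhaustive likelihood grid search on small data and against an independent
GLM implementation; Fisher's exact p against hypergeometric enumeration.
These sizes were chosen to give tight Monte Carlo error at interactive
runtimes; `analysis/05_synthetic_checks.py` runs reduced-replicate versions
of the same checks.

## Known limitations

- Doses are stored as printed: several source studies quoted D1cc rather
  than D_max or slightly different α/β ratios; no harmonisation is applied.
- The study-table refit uses study-median doses, flattening the
  within-study dose gradient; its dose coefficient is attenuated relative
  to a unit-level fit.
- Clustering is handled only through the block bootstrap; no random-effects
  meta-regression is attempted.
- The binary outcome carries no time-to-event structure; differing
  follow-up between studies is unmodelled heterogeneity.
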