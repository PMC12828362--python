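# oesotox

Cumulative oesophageal dose / high-grade toxicity modelling for thoracic
re-irradiation.

Re-irradiation of recurrent lung and oesophageal cancer accumulates dose in
the oesophagus across two radiotherapy courses, and grade ≥3 toxicity
(oesophagitis, stenosis, haemorrhage, perforation, tracheo-oesophageal
fistula) is the dose-limiting risk. Individual retrospective series are too
small to model this; `oesotox` implements the pooled-analysis toolchain for
radiotherapy physicists and outcome modellers: linear-quadratic EQD2
conversion and accumulation, a mixed patient-level/grouped logistic NTCP
model, leave-one-study-out model selection, inversion to iso-risk dose
constraints with delta-method and study-level block-bootstrap confidence
intervals, and decile calibration — together with a transcribed 21-study
pooled dataset (505 patients) and a seeded synthetic-cohort generator.

The core model is logistic in cumulative oesophageal D_max (CD, Gy EQD2)
and concurrent chemotherapy (CC):

    P(≥G3 toxicity) = 1 / (1 + exp(−(β₀ + β_dose·CD + β_chemo·CC)))

Patient records enter the likelihood as Bernoulli terms, grouped studies as
binomial(n, events) terms at the study's median dose and chemotherapy rate.
A fitted (or published) model inverts in closed form to the dose predicting
any target toxicity rate:

    CD(p, CC) = (logit(p) − β₀ − β_chemo·CC) / β_dose

See `docs/methods.md` for the full statistical account.

## Worked example

Invert the published multivariable model (β₀ = −7.0065, β_dose = 0.0431 per
Gy, β_chemo = 2.2065) to dose constraints:

```python
>>> from oesotox import published_model, invert_dose, chemo_dose_shift
>>> m = published_model()
>>> round(invert_dose(m, 0.05, chemo=0), 1)   # 5% risk, no chemotherapy
94.2
>>> round(invert_dose(m, 0.05, chemo=1), 1)   # 5% risk, with chemotherapy
43.1
>>> round(chemo_dose_shift(m), 1)             # constant shift between curves, Gy
51.2
```

A cumulative oesophageal D_max of 94.2 Gy₃ EQD2 predicts a 5 % grade ≥3
toxicity rate without concurrent chemotherapy; chemotherapy shifts every
iso-risk dose down by 51.2 Gy.

Fit the model to the packaged study table and rank models by
leave-one-study-out held-out negative log-likelihood:

```bash
$ oesotox cv --fixture
     model  total_heldout_nll  n_folds
dose+chemo          89.255768       18
      dose         117.418756       18
```

The dose+chemotherapy model generalises better across studies (lower
held-out NLL) than dose alone. The full pipeline — median-split tests,
univariable screen (gate p < 0.2), multivariable fit, LOOCV, constraint
inversion with 2000 block-bootstrap replicates, decile calibration — runs
with:

```bash
oesotox run --fixture --seed 1 --out-dir results/
```

or, as numbered narrative drivers, `python analysis/01_fixture_overview.py`
through `analysis/05_synthetic_checks.py`.

## Data schemas

Patient-level CSV (`NA`/`NR` = missing):
`patient_id, study_id, cdmax_gy_eqd2, chemo, interval_months, event,
event_timing, event_grade`

Grouped cohort CSV:
`study_id, n, events, cdmax_rep_gy_eqd2, chemo_fraction,
interval_rep_months, followup_rep_months`

The packaged fixture (`oesotox.builtin_fixture()`) ships both granularities
plus the raw event-type table; transcription and reconciliation notes are
in `src/oesotox/data/provenance.md`.

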