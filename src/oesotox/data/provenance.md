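# Fixture provenance

The two CSVs in this directory transcribe the study-level summary tables of a
published pooled dose/toxicity analysis of thoracic re-irradiation
(21 retrospective cohorts, 505 patients in total, treated 1996–2017).

`table1_cohorts.csv` — one row per study: sample size, grouped count of
grade ≥3 oesophageal events, median cumulative oesophageal D_max in EQD2
(alpha/beta as published; Gy_3 for late, Gy_10 for acute outcomes, stored as
printed without harmonisation), concurrent-chemotherapy rate with
re-irradiation, median inter-course interval, and median follow-up.
"NR" marks values the source studies did not record; they are kept as
explicit missing, never zero.

`table2_events.csv` — one row per (study, timing, grade, category) cell of
the event-type table: 57 raw events across 11 studies. Eight patients had
both an acute and a late event (one in the Yamaguchi cohort, seven in the
Chen cohort), so the per-patient grouped total is 49.

Reconciliation rules applied during transcription:

- Where a study appears in the event table, its integer event count is the
  source of truth; otherwise the grouped count is `round(n * toxicity% /
  100)` from the study table.
- Schlampp: the study table's printed 4.8% of 62 would round to 3 events,
  but the event table lists exactly 2 (one late G3 stenosis, one late G4
  tracheo-oesophageal fistula); 2 is stored.
- Katano: 16.7% of 4 patients (0.67) vs 1 listed late G3 dysphagia event;
  both round to 1.
- Chen grouped grades 2–4 together in its source report, so a small number
  of its 19 acute "G3" events may in truth be grade 2; counts are stored as
  printed.
- Several source studies quoted D1cc rather than D_max, or slightly
  different alpha/beta ratios; doses are stored as printed, uncorrected.
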