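#!/usr/bin/env python
"""Load the packaged 21-study dataset and tabulate its structure.

Reports the conservation totals (505 patients, 57 raw / 49 per-patient
grade >=3 events), the event-type breakdown, and the median-split
contingency tests of dose, chemotherapy and interval against toxicity on
the reconstructed patient-level expansion.
"""

from pathlib import Path

import pandas as pd

from oesotox.pipeline import _median_split_tests
from oesotox.study_data import builtin_fixture

OUT = Path("results")
OUT.mkdir(exist_ok=True)

cohorts, events, patients = builtin_fixture()

summary = pd.DataFrame(
    [
        {
            "study_id": c.study_id,
            "n": c.n,
            "events": c.events,
            "cdmax_rep_gy_eqd2": c.cdmax_rep,
            "chemo_fraction": c.chemo_fraction,
            "interval_rep_months": c.interval_rep_months,
        }
        for c in cohorts
    ]
)
summary.to_csv(OUT / "fixture_studies.csv", index=False)

raw = sum(e.count for e in events)
grouped = sum(c.events for c in cohorts)
print(f"{len(cohorts)} studies, {summary['n'].sum()} patients")
print(f"{raw} raw grade>=3 events; {grouped} affected patients "
      f"({raw - grouped} had both an acute and a late event)")

by_cat = pd.Series(
    {cat: sum(e.count for e in events if e.category == cat)
     for cat in ("perforation_tof", "oesophagitis_dysphagia", "bleeding", "stenosis")}
)
acute_g3 = sum(e.count for e in events if e.timing == "acute" and e.grade == 3)
print("\nEvent categories:")
print(by_cat.to_string())
print(f"acute G3 share: {100 * acute_g3 / raw:.1f}% of all raw events")
by_cat.rename("count").to_csv(OUT / "event_categories.csv")

tests = _median_split_tests(patients)
tests.to_csv(OUT / "median_split_tests.csv", index=False)
print("\nMedian-split contingency tests (reconstructed patient expansion):")
print(tests.to_string(index=False))
print("\nAll three candidate predictors associate with toxicity at the "
      "median split, motivating the regression screen (02).")
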