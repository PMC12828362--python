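"""Model diagnostics: decile calibration, cutoff discrimination, 2x2 tests.

Calibration follows the decile convention: units are ranked by modelled
risk (no pre-specified risk bands), cut into ten equal-count bins, and the
mean predicted rate per bin is compared with the observed event rate; the
agreement over the ten pairs is summarised by a Pearson correlation (whose
p-value uses the t distribution with 8 degrees of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import FittedModel, units_frame
from .study_data import CohortSummary, PatientRecord

__all__ = [
    "CalibrationBin",
    "decile_calibration",
    "threshold_validation",
    "ThresholdResult",
    "ContingencyResult",
    "contingency_test",
]


@dataclass(frozen=True)
class CalibrationBin:
    bin_index: int  # 1 (lowest risk) .. 10
    n_units: int  # trials in the bin (patients, or cohort patients)
    predicted_rate: float
    observed_rate: float

    def __post_init__(self) -> None:
        if not 1 <= self.bin_index <= 10:
            raise ValueError("bin_index must lie in 1..10")
        if not (0 <= self.predicted_rate <= 1 and 0 <= self.observed_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


def decile_calibration(
    model: FittedModel,
    data: Sequence[PatientRecord | CohortSummary],
) -> tuple[list[CalibrationBin], float, float]:
    """Equal-count decile calibration of modelled vs observed toxicity rates.

    Complete-case units (for the model's covariates) are sorted by predicted
    risk — ties broken by a stable sort on (risk, position), so grouped data
    with many identical predictions bin deterministically — and cut into 10
    bins of equal unit count, any remainder spread over the lowest bins.
    Returns the bins, the Pearson r over the 10 (mean predicted, observed)
    pairs, and its two-sided p.
    """
    df = units_frame(data, model.spec.cohort_chemo_coding)
    df = df.dropna(subset=list(model.spec.covariates)).reset_index(drop=True)
    if len(df) < 10:
        raise ValueError("decile calibration needs at least 10 complete-case units")

    preds = np.array(
        [
            model.predict(**{c: row[c] for c in model.spec.covariates})
            for _, row in df.iterrows()
        ]
    )
    if np.ptp(preds) == 0:
        raise ValueError(
            "all predicted risks identical; decile binning is degenerate"
        )
    order = np.argsort(preds, kind="stable")

    n_units = len(df)
    base, remainder = divmod(n_units, 10)
    sizes = [base + 1 if i < remainder else base for i in range(10)]

    bins: list[CalibrationBin] = []
    pos = 0
    for i, size in enumerate(sizes, start=1):
        idx = order[pos : pos + size]
        pos += size
        trials = df.loc[idx, "n"].to_numpy(float)
        events = df.loc[idx, "y"].to_numpy(float)
        p = preds[idx]
        bins.append(
            CalibrationBin(
                bin_index=i,
                n_units=int(trials.sum()),
                predicted_rate=float(np.sum(p * trials) / trials.sum()),
                observed_rate=float(events.sum() / trials.sum()),
            )
        )
    pred_rates = [b.predicted_rate for b in bins]
    obs_rates = [b.observed_rate for b in bins]
    r, p_value = stats.pearsonr(pred_rates, obs_rates)
    return bins, float(r), float(p_value)


@dataclass(frozen=True)
class ThresholdResult:
    cutoff: float
    rate_above: float | None  # None when the group is empty
    rate_below: float | None
    n_above: int
    n_below: int
    events_above: int
    events_below: int


def threshold_validation(
    patients: Sequence[PatientRecord], cutoff: float
) -> ThresholdResult:
    """Observed grade >=3 toxicity rates strictly above vs at-or-below a dose cutoff.

    An empty group reports its rate as ``None`` (undefined), never zero.
    """
    above = [p for p in patients if p.cdmax > cutoff]
    below = [p for p in patients if p.cdmax <= cutoff]
    ev_above = sum(p.event for p in above)
    ev_below = sum(p.event for p in below)
    return ThresholdResult(
        cutoff=cutoff,
        rate_above=ev_above / len(above) if above else None,
        rate_below=ev_below / len(below) if below else None,
        n_above=len(above),
        n_below=len(below),
        events_above=ev_above,
        events_below=ev_below,
    )


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray  # 2x2 counts: rows = predictor groups, cols = outcome 0/1
    test: str  # "chi_squared" or "fisher_exact"
    statistic: float | None
    p_value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "table", np.asarray(self.table, int))
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def contingency_test(
    predictor_labels: Sequence, outcomes: Sequence[int]
) -> ContingencyResult:
    """2x2 association test between a binary predictor and binary outcome.

    Uses the chi-squared test (without continuity correction) when every
    expected cell count is >= 5, otherwise Fisher's exact test — the
    conventional switching rule.  A table with a zero margin degenerates to
    Fisher with p = 1 (and a warning): independence cannot be assessed.
    """
    labels = np.asarray(predictor_labels)
    outcome = np.asarray(outcomes, int)
    if labels.shape != outcome.shape or labels.size == 0:
        raise ValueError("predictor and outcome must be equal-length, non-empty")
    if set(np.unique(outcome)) - {0, 1}:
        raise ValueError("outcomes must be binary 0/1")
    groups = np.unique(labels)
    if len(groups) > 2:
        raise ValueError("predictor must be binary")
    table = np.zeros((2, 2), dtype=int)
    for gi, g in enumerate(groups):
        mask = labels == g
        table[gi, 0] = int(np.sum(outcome[mask] == 0))
        table[gi, 1] = int(np.sum(outcome[mask] == 1))

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        warnings.warn(
            "contingency table has a zero margin; association undefined (p = 1)",
            stacklevel=2,
        )
        return ContingencyResult(table=table, test="fisher_exact", statistic=None, p_value=1.0)

    expected = np.outer(row, col) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        return ContingencyResult(table=table, test="fisher_exact", statistic=None, p_value=float(p))
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ContingencyResult(
        table=table, test="chi_squared", statistic=float(stat), p_value=float(p)
    )
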