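"""Linear-quadratic dose conversion to EQD2 and accumulation across courses.

The equivalent dose in 2-Gy fractions (EQD2) rescales a fractionated schedule
of total dose ``D`` delivered in fractions of size ``d`` so that schedules
with different fraction sizes become comparable on a common biological scale:

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

``alpha/beta`` (Gy) is the tissue-specific linear-quadratic parameter: low
(3 Gy) for late-responding normal tissue, high (10 Gy) for acute effects.
A dose expressed with alpha/beta = 3 is written "Gy_3"; values computed with
different ratios live on different scales, so :class:`Eqd2Dose` carries its
ratio and refuses arithmetic across ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

__all__ = [
    "TimingClass",
    "TreatmentCourse",
    "Eqd2Dose",
    "alpha_beta_for",
    "eqd2",
    "cumulative_eqd2",
    "ALPHA_BETA_ACUTE",
    "ALPHA_BETA_LATE",
]

#: Conventional alpha/beta for acute oesophageal effects (Gy).
ALPHA_BETA_ACUTE = 10.0
#: Conventional alpha/beta for late oesophageal effects (Gy).
ALPHA_BETA_LATE = 3.0


class TimingClass(str, Enum):
    """Toxicity timing class governing the alpha/beta choice.

    Events within 3 months of re-irradiation are acute (alpha/beta = 10 Gy),
    later events are late (alpha/beta = 3 Gy).
    """

    ACUTE = "acute"
    LATE = "late"


def alpha_beta_for(timing: TimingClass | str) -> float:
    """Deterministic timing-class -> alpha/beta (Gy) mapping."""
    timing = TimingClass(timing)
    return ALPHA_BETA_ACUTE if timing is TimingClass.ACUTE else ALPHA_BETA_LATE


@dataclass(frozen=True)
class TreatmentCourse:
    """One radiotherapy course: physical dose and fractionation.

    Parameters
    ----------
    total_dose:
        Physical total dose in Gy, >= 0.
    dose_per_fraction:
        Physical dose per fraction in Gy; must be > 0 whenever
        ``total_dose`` > 0.
    n_fractions:
        Number of fractions; checked against ``total_dose`` within a small
        rounding tolerance when both are supplied.
    timing_class:
        Optional default timing class for alpha/beta selection.
    """

    total_dose: float
    dose_per_fraction: float
    n_fractions: int | None = None
    timing_class: TimingClass | None = None

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise ValueError(f"total_dose must be >= 0, got {self.total_dose}")
        if self.total_dose > 0 and self.dose_per_fraction <= 0:
            raise ValueError(
                "dose_per_fraction must be > 0 for a non-zero course, got "
                f"{self.dose_per_fraction}"
            )
        if self.n_fractions is not None:
            if self.n_fractions <= 0:
                raise ValueError("n_fractions must be a positive integer")
            implied = self.dose_per_fraction * self.n_fractions
            if self.total_dose > 0 and not math.isclose(
                implied, self.total_dose, rel_tol=1e-3, abs_tol=0.05
            ):
                raise ValueError(
                    f"total_dose {self.total_dose} Gy inconsistent with "
                    f"{self.n_fractions} x {self.dose_per_fraction} Gy = {implied} Gy"
                )


@dataclass(frozen=True)
class Eqd2Dose:
    """An EQD2 value annotated with the alpha/beta ratio it was computed under.

    Addition of two values with different ratios raises, so Gy_3 and Gy_10
    quantities can never be silently mixed.
    """

    value: float
    alpha_beta: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"EQD2 value must be >= 0, got {self.value}")
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be > 0, got {self.alpha_beta}")

    def __add__(self, other: "Eqd2Dose") -> "Eqd2Dose":
        if not isinstance(other, Eqd2Dose):
            return NotImplemented
        if other.alpha_beta != self.alpha_beta:
            raise ValueError(
                f"cannot combine EQD2 doses with different alpha/beta ratios "
                f"(Gy_{self.alpha_beta:g} + Gy_{other.alpha_beta:g})"
            )
        return Eqd2Dose(self.value + other.value, self.alpha_beta)

    __radd__ = __add__

    def __str__(self) -> str:
        return f"{self.value:.1f} Gy_{self.alpha_beta:g} EQD2"


def eqd2(course: TreatmentCourse, alpha_beta: float) -> Eqd2Dose:
    """Convert one course to EQD2 under the given alpha/beta ratio.

    Returns ``D * (d + alpha/beta) / (2 + alpha/beta)``. A course delivered
    at exactly 2 Gy per fraction is a fixed point for every ratio.
    """
    if alpha_beta <= 0:
        raise ValueError(f"alpha_beta must be > 0, got {alpha_beta}")
    if course.total_dose == 0:
        return Eqd2Dose(0.0, alpha_beta)
    value = course.total_dose * (course.dose_per_fraction + alpha_beta) / (2.0 + alpha_beta)
    return Eqd2Dose(value, alpha_beta)


def cumulative_eqd2(
    courses: Iterable[TreatmentCourse], alpha_beta: float
) -> Eqd2Dose:
    """Sum per-course EQD2 values on a common alpha/beta scale.

    EQD2 accumulation is plain addition — no repopulation/time factor and no
    recovery discount for the inter-course interval (the interval is handled
    downstream as a candidate regression covariate, not as a dose modifier).
    Order-independent; an empty course list warns and returns 0.
    """
    courses = list(courses)
    if not courses:
        warnings.warn("cumulative_eqd2 called with no courses; returning 0", stacklevel=2)
        return Eqd2Dose(0.0, alpha_beta)
    total = Eqd2Dose(0.0, alpha_beta)
    for course in courses:
        total = total + eqd2(course, alpha_beta)
    return total
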