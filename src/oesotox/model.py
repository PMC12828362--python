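"""Maximum-likelihood logistic dose-response fitting on mixed-granularity data.

The pooled likelihood treats each patient-level record as a Bernoulli trial
at its own covariates and each grouped study as a binomial(n, events) draw at
the study's representative covariates (median cumulative EQD2 dose, fractional
chemotherapy rate).  The two granularities are interchangeable in the
likelihood: a cohort of n identical patients contributes exactly the same
kernel as the n patient records.

Fitting is Newton-Raphson on the binomial log-likelihood kernel

    l(beta) = sum_i [ y_i log p_i + (n_i - y_i) log(1 - p_i) ],
    p_i = expit(x_i' beta)

with the observed-information covariance (X' W X)^{-1} at the optimum.
Complete separation is detected by coefficient divergence and flagged rather
than silently returned; no penalisation is applied, as the downstream
analyses use plain ML estimates.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .study_data import CohortSummary, PatientRecord

__all__ = [
    "ModelSpec",
    "FittedModel",
    "CvResult",
    "FitError",
    "SeparationError",
    "units_frame",
    "fit_logistic",
    "wald_p",
    "screen_univariable",
    "ScreenResult",
    "loocv_by_cohort",
    "PUBLISHED_COEFFICIENTS",
    "published_model",
]

COVARIATES = ("dose", "chemo", "interval")

#: Published multivariable fit: intercept, dose (per Gy EQD2), chemo.
PUBLISHED_COEFFICIENTS = (-7.0065, 0.0431, 2.2065)

_SEPARATION_BOUND = 50.0
_GRAD_TOL = 1e-8
_MAX_ITER = 100


class FitError(ValueError):
    """The requested model cannot be fitted on the supplied data."""


class SeparationError(FitError):
    """Complete (quasi-)separation: the MLE diverges."""


@dataclass(frozen=True)
class ModelSpec:
    """Ordered covariate subset for a logistic model (logit link, fixed).

    ``cohort_chemo_coding`` controls how a grouped study's chemotherapy
    enters: as its fractional rate (default) or dichotomised at 0.5.
    """

    covariates: tuple[str, ...]
    cohort_chemo_coding: Literal["fraction", "dichotomized"] = "fraction"

    def __post_init__(self) -> None:
        unknown = set(self.covariates) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariate(s) {sorted(unknown)}")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates in spec")

    @property
    def names(self) -> tuple[str, ...]:
        return ("intercept",) + tuple(self.covariates)

    def label(self) -> str:
        return "+".join(self.covariates) if self.covariates else "intercept-only"


@dataclass(frozen=True)
class FittedModel:
    """A fitted (or externally supplied) logistic dose-response model."""

    spec: ModelSpec
    coefficients: np.ndarray  # (intercept, then spec covariates), logit scale
    covariance: np.ndarray | None
    log_likelihood: float | None
    n_units: int
    n_dropped: int = 0
    converged: bool = True
    diagnostic: str = ""
    data_hash: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, float))
        if len(self.coefficients) != len(self.spec.names):
            raise ValueError("coefficient vector does not match spec")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, float)
            if cov.shape != (len(self.coefficients),) * 2:
                raise ValueError("covariance dimensions do not match coefficients")
            object.__setattr__(self, "covariance", cov)

    def coef(self, name: str) -> float:
        try:
            return float(self.coefficients[self.spec.names.index(name)])
        except ValueError:
            raise KeyError(f"model has no term {name!r}") from None

    def se(self, name: str) -> float:
        if self.covariance is None:
            raise ValueError("model carries no covariance")
        i = self.spec.names.index(name)
        return float(np.sqrt(self.covariance[i, i]))

    def linear_predictor(self, **covariates: float) -> float:
        eta = self.coefficients[0]
        for j, name in enumerate(self.spec.covariates, start=1):
            if name not in covariates:
                raise KeyError(f"value for covariate {name!r} required")
            eta += self.coefficients[j] * covariates[name]
        return float(eta)

    def predict(self, **covariates: float) -> float:
        """Modelled grade >=3 toxicity probability at the given covariates."""
        return float(expit(self.linear_predictor(**covariates)))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.spec.names:
            se = self.se(name) if self.covariance is not None else np.nan
            beta = self.coef(name)
            rows.append(
                {
                    "term": name,
                    "coef": beta,
                    "se": se,
                    "z": beta / se if se and not math.isnan(se) else np.nan,
                    "p": 2 * norm.sf(abs(beta / se)) if se and not math.isnan(se) else np.nan,
                }
            )
        return pd.DataFrame(rows)


def published_model() -> FittedModel:
    """The published multivariable model (dose in Gy EQD2 + chemotherapy).

    Coefficients are transcribed from the published fit; no covariance was
    published, so Wald intervals are unavailable on this object.
    """
    return FittedModel(
        spec=ModelSpec(covariates=("dose", "chemo")),
        coefficients=np.array(PUBLISHED_COEFFICIENTS),
        covariance=None,
        log_likelihood=None,
        n_units=505,
        converged=True,
        diagnostic="published coefficients; no covariance available",
    )


# ---------------------------------------------------------------------------
# Unit table construction


def units_frame(
    data: Sequence[PatientRecord | CohortSummary],
    cohort_chemo_coding: str = "fraction",
) -> pd.DataFrame:
    """Flatten mixed records into the likelihood's unit table.

    Columns: study_id, n (trials), y (events), dose, chemo, interval,
    is_patient.  Missing covariates are NaN; filtering is left to the fit.
    """
    rows = []
    for item in data:
        if isinstance(item, PatientRecord):
            rows.append(
                {
                    "study_id": item.study_id,
                    "n": 1,
                    "y": item.event,
                    "dose": item.cdmax,
                    "chemo": np.nan if item.chemo is None else float(item.chemo),
                    "interval": np.nan
                    if item.interval_months is None
                    else item.interval_months,
                    "is_patient": True,
                }
            )
        elif isinstance(item, CohortSummary):
            if item.chemo_fraction is None:
                chemo = np.nan
            elif cohort_chemo_coding == "dichotomized":
                chemo = float(item.chemo_fraction >= 0.5)
            else:
                chemo = item.chemo_fraction
            rows.append(
                {
                    "study_id": item.study_id,
                    "n": item.n,
                    "y": item.events,
                    "dose": item.cdmax_rep,
                    "chemo": chemo,
                    "interval": np.nan
                    if item.interval_rep_months is None
                    else item.interval_rep_months,
                    "is_patient": False,
                }
            )
        else:
            raise TypeError(f"cannot use {type(item).__name__} as a likelihood unit")
    return pd.DataFrame(
        rows, columns=["study_id", "n", "y", "dose", "chemo", "interval", "is_patient"]
    )


def _loglik_kernel(beta: np.ndarray, X: np.ndarray, n: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log(p) and log(1-p) in a numerically stable form
    return float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))


def _hash_units(df: pd.DataFrame) -> str:
    payload = df[["study_id", "n", "y", "dose", "chemo", "interval"]].to_csv(index=False)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _newton(
    X: np.ndarray, n: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None, float, bool, str]:
    """Newton-Raphson core on standardized columns.

    Returns (beta, covariance, log-likelihood, converged, diagnostic); the
    covariance is the inverse observed information at the optimum, None when
    not converged.
    """
    if y.sum() == 0 or (n - y).sum() == 0:
        raise FitError("data contain no events or no non-events; model is degenerate")
    # standardize columns for numerical conditioning; back-transform after
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    scale[0] = 1.0
    Xs = X / scale

    beta = np.zeros(X.shape[1])
    ll = _loglik_kernel(beta, Xs, n, y)
    converged = False
    diagnostic = ""
    for _ in range(_MAX_ITER):
        p = expit(Xs @ beta)
        grad = Xs.T @ (y - n * p)
        w = n * p * (1 - p)
        H = Xs.T @ (Xs * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            diagnostic = "singular information matrix"
            break
        # step-halving to keep the likelihood non-decreasing
        for _ in range(30):
            candidate = beta + step
            ll_new = _loglik_kernel(candidate, Xs, n, y)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll = candidate, ll_new
        if np.max(np.abs(beta / scale)) > _SEPARATION_BOUND:
            diagnostic = (
                "complete separation suspected: coefficients diverging "
                f"(|beta| > {_SEPARATION_BOUND:g})"
            )
            break
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break
    else:
        diagnostic = f"no convergence within {_MAX_ITER} iterations"

    beta_orig = beta / scale
    covariance = None
    if converged:
        p = expit(X @ beta_orig)
        w = n * p * (1 - p)
        H = X.T @ (X * w[:, None])
        try:
            covariance = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            converged = False
            diagnostic = "observed information singular at the optimum"
    return beta_orig, covariance, _loglik_kernel(beta_orig, X, n, y), converged, diagnostic


def fit_logistic(
    data: Sequence[PatientRecord | CohortSummary] | pd.DataFrame,
    spec: ModelSpec,
) -> FittedModel:
    """Maximum-likelihood logistic fit on mixed Bernoulli/binomial units.

    Units missing any of the spec's covariates are dropped (complete-case,
    counted in ``n_dropped``).  Raises :class:`FitError` when the filtered
    data have no events or no non-events, and flags (without returning
    silently) complete separation.
    """
    df = data if isinstance(data, pd.DataFrame) else units_frame(
        data, spec.cohort_chemo_coding
    )
    if df.empty:
        raise FitError("no units supplied")
    needed = list(spec.covariates)
    complete = df.dropna(subset=needed) if needed else df
    n_dropped = len(df) - len(complete)
    if complete.empty:
        raise FitError("no complete-case units for covariates " + ", ".join(needed))

    n = complete["n"].to_numpy(float)
    y = complete["y"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(complete))] + [complete[c].to_numpy(float) for c in needed]
    )
    beta_orig, covariance, ll, converged, diagnostic = _newton(X, n, y)

    return FittedModel(
        spec=spec,
        coefficients=beta_orig,
        covariance=covariance,
        log_likelihood=ll,
        n_units=len(complete),
        n_dropped=n_dropped,
        converged=converged,
        diagnostic=diagnostic,
        data_hash=_hash_units(complete),
    )


def wald_p(model: FittedModel, covariate: str) -> float:
    """Two-sided normal (Wald) test of one coefficient against zero."""
    if not model.converged:
        raise FitError("Wald test requires a converged model")
    z = model.coef(covariate) / model.se(covariate)
    return float(2 * norm.sf(abs(z)))


@dataclass(frozen=True)
class ScreenResult:
    table: pd.DataFrame  # candidate, coef, se, p, error
    selected: tuple[str, ...]
    gate: float


def screen_univariable(
    data: Sequence[PatientRecord | CohortSummary],
    candidates: Sequence[str] = COVARIATES,
    gate: float = 0.2,
    cohort_chemo_coding: str = "fraction",
) -> ScreenResult:
    """Fit one univariable model per candidate; keep those with Wald p < gate.

    Per-candidate fit failures are recorded in the table, not raised, so one
    degenerate candidate cannot abort the screen.
    """
    rows = []
    selected = []
    for cand in candidates:
        spec = ModelSpec(covariates=(cand,), cohort_chemo_coding=cohort_chemo_coding)
        try:
            m = fit_logistic(data, spec)
            if not m.converged:
                raise FitError(m.diagnostic or "did not converge")
            p = wald_p(m, cand)
            rows.append(
                {"candidate": cand, "coef": m.coef(cand), "se": m.se(cand), "p": p, "error": ""}
            )
            if p < gate:
                selected.append(cand)
        except FitError as exc:
            rows.append(
                {"candidate": cand, "coef": np.nan, "se": np.nan, "p": np.nan, "error": str(exc)}
            )
    return ScreenResult(
        table=pd.DataFrame(rows), selected=tuple(selected), gate=gate
    )


# ---------------------------------------------------------------------------
# Leave-one-cohort-out cross-validation


@dataclass(frozen=True)
class CvResult:
    """Held-out negative log-likelihood per left-out study (lower = better)."""

    spec: ModelSpec
    fold_scores: dict = field(default_factory=dict)  # study_id -> held-out NLL
    excluded_folds: tuple[str, ...] = ()

    @property
    def total_score(self) -> float:
        return float(sum(self.fold_scores.values()))


def loocv_by_cohort(
    data: Sequence[PatientRecord | CohortSummary],
    specs: Sequence[ModelSpec],
) -> list[CvResult]:
    """Leave-one-study-out cross-validation over candidate model specs.

    For each spec and each study: fit on all other studies, score the held-out
    study by its negative log-likelihood kernel under that fit, and sum over
    studies.  Folds where any spec fails to fit or converge are excluded for
    every spec, so totals stay comparable.  Results are returned ranked by
    total score (best first).
    """
    frames = {spec: units_frame(data, spec.cohort_chemo_coding) for spec in specs}
    study_ids = sorted(frames[specs[0]]["study_id"].unique())
    if len(study_ids) < 2:
        raise FitError("leave-one-cohort-out needs at least 2 studies")

    raw_scores: dict[ModelSpec, dict[str, float]] = {spec: {} for spec in specs}
    bad_folds: set[str] = set()
    for spec in specs:
        df = frames[spec]
        for sid in study_ids:
            train = df[df["study_id"] != sid]
            test = df[df["study_id"] == sid].dropna(subset=list(spec.covariates))
            if test.empty:
                bad_folds.add(sid)
                continue
            try:
                m = fit_logistic(train, spec)
                if not m.converged:
                    raise FitError(m.diagnostic)
            except FitError:
                bad_folds.add(sid)
                continue
            X = np.column_stack(
                [np.ones(len(test))]
                + [test[c].to_numpy(float) for c in spec.covariates]
            )
            nll = -_loglik_kernel(
                m.coefficients, X, test["n"].to_numpy(float), test["y"].to_numpy(float)
            )
            raw_scores[spec][sid] = nll

    results = [
        CvResult(
            spec=spec,
            fold_scores={
                sid: s for sid, s in raw_scores[spec].items() if sid not in bad_folds
            },
            excluded_folds=tuple(sorted(bad_folds)),
        )
        for spec in specs
    ]
    return sorted(results, key=lambda r: r.total_score)
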