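"""Iso-risk dose constraints: model inversion, Wald and block-bootstrap CIs.

A fitted logistic model in cumulative dose CD (Gy EQD2) and concurrent
chemotherapy CC inverts in closed form: the dose predicted to give a target
grade >=3 toxicity rate p is

    CD(p, CC) = (logit(p) - beta0 - beta_chemo * CC) / beta_dose.

Two interval flavours are provided.  The Wald interval applies the delta
method to this inverse prediction using the fitted covariance.  The block
bootstrap resamples whole study cohorts with replacement (preserving the
between-study clustering/overdispersion of pooled data), refits and
re-inverts per replicate, and takes the 2.5th/97.5th percentiles.  Bounds
are deliberately never truncated at zero: a strongly left-shifted
with-chemotherapy curve can legitimately produce a negative lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import norm

from .model import FitError, FittedModel, ModelSpec, _newton, fit_logistic, units_frame
from .study_data import CohortSummary, PatientRecord

__all__ = [
    "DoseConstraint",
    "invert_dose",
    "wald_ci_dose",
    "block_bootstrap_ci",
    "chemo_dose_shift",
    "BootstrapDiagnostics",
]


@dataclass(frozen=True)
class DoseConstraint:
    """One iso-risk dose row: ML dose with Wald and/or bootstrap intervals."""

    target_rate: float
    chemo: int
    dose_ml: float
    wald_ci: tuple[float, float] | None = None
    bootstrap_ci: tuple[float, float] | None = None
    n_replicates_requested: int | None = None
    n_replicates_converged: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.target_rate < 1:
            raise ValueError("target_rate must lie in (0, 1)")
        if self.wald_ci is not None and not (
            self.wald_ci[0] <= self.dose_ml <= self.wald_ci[1]
        ):
            raise ValueError("Wald interval must bracket the ML dose")


def _dose_chemo_betas(model: FittedModel) -> tuple[float, float, float]:
    if "dose" not in model.spec.covariates:
        raise FitError("model has no dose term; cannot invert")
    b0 = model.coef("intercept")
    bd = model.coef("dose")
    bc = model.coef("chemo") if "chemo" in model.spec.covariates else 0.0
    return b0, bd, bc


def invert_dose(model: FittedModel, target_rate: float, chemo: int = 0) -> float:
    """Closed-form iso-risk dose (Gy EQD2) at the target toxicity rate."""
    if not 0 < target_rate < 1:
        raise ValueError(f"target_rate must lie in (0, 1), got {target_rate}")
    b0, bd, bc = _dose_chemo_betas(model)
    if bd == 0:
        raise FitError("dose coefficient is zero; iso-risk dose undefined")
    return float((logit(target_rate) - b0 - bc * chemo) / bd)


def chemo_dose_shift(model: FittedModel) -> float:
    """Horizontal shift (Gy) between the no-chemo and with-chemo curves.

    Equals beta_chemo / beta_dose and is independent of the target rate:
    invert_dose(p, 0) - invert_dose(p, 1) for every p.
    """
    b0, bd, bc = _dose_chemo_betas(model)
    if "chemo" not in model.spec.covariates:
        raise FitError("model has no chemotherapy term")
    if bd == 0:
        raise FitError("dose coefficient is zero; shift undefined")
    return float(bc / bd)


def wald_ci_dose(
    model: FittedModel, target_rate: float, chemo: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Delta-method interval for the inverted iso-risk dose.

    The variance of CD = (logit(p) - beta0 - beta_c*CC)/beta_d follows from
    the gradient g = (-1/beta_d, -CD/beta_d, -CC/beta_d) applied to the
    fitted covariance; normal quantiles give the interval.
    """
    if model.covariance is None:
        raise FitError("model carries no covariance; Wald interval unavailable")
    if not model.converged:
        raise FitError("Wald interval requires a converged model")
    b0, bd, bc = _dose_chemo_betas(model)
    dose = invert_dose(model, target_rate, chemo)
    names = model.spec.names
    g = np.zeros(len(names))
    g[names.index("intercept")] = -1.0 / bd
    g[names.index("dose")] = -dose / bd
    if "chemo" in names:
        g[names.index("chemo")] = -chemo / bd
    var = float(g @ model.covariance @ g)
    if var < 0:
        raise FitError("negative delta-method variance (covariance not PSD)")
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (dose - half, dose + half)


@dataclass(frozen=True)
class BootstrapDiagnostics:
    n_requested: int
    n_converged: int
    n_separated_or_failed: int
    seed: int


def block_bootstrap_ci(
    data: Sequence[PatientRecord | CohortSummary],
    spec: ModelSpec,
    target_rates: Sequence[float],
    chemo_levels: Sequence[int] = (0, 1),
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[list[DoseConstraint], BootstrapDiagnostics]:
    """Study-level block-bootstrap percentile intervals for iso-risk doses.

    Each replicate resamples whole studies with replacement (resample size =
    observed number of studies), refits the model on the resampled units and
    inverts at every (rate, chemo) combination.  The interval is the
    (1-level)/2 and 1-(1-level)/2 percentiles of the converged replicates;
    replicates that separate or fail to converge are dropped and counted.
    Reproducible under ``seed``; bounds are not truncated at zero.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    df = units_frame(data, spec.cohort_chemo_coding)
    study_ids = np.array(sorted(df["study_id"].unique()))
    if len(study_ids) < 1:
        raise FitError("no studies in data")

    observed = fit_logistic(df, spec)
    if not observed.converged:
        raise FitError(f"observed-data fit failed: {observed.diagnostic}")
    combos = [(p, c) for p in target_rates for c in chemo_levels]
    point = {pc: invert_dose(observed, *pc) for pc in combos}
    wald = {pc: wald_ci_dose(observed, *pc, level=level) for pc in combos}

    # per-study complete-case design blocks, resampled as whole studies
    complete = df.dropna(subset=list(spec.covariates))
    blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for sid, sub in complete.groupby("study_id"):
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[c].to_numpy(float) for c in spec.covariates]
        )
        blocks[sid] = (X, sub["n"].to_numpy(float), sub["y"].to_numpy(float))
    i_dose = 1 + spec.covariates.index("dose")
    i_chemo = 1 + spec.covariates.index("chemo") if "chemo" in spec.covariates else None
    logits = {pc: logit(pc[0]) for pc in combos}

    draws: dict[tuple[float, int], list[float]] = {pc: [] for pc in combos}
    n_failed = 0
    for _ in range(B):
        chosen = rng.choice(study_ids, size=len(study_ids), replace=True)
        parts = [blocks[sid] for sid in chosen if sid in blocks]
        if not parts:
            n_failed += 1
            continue
        Xb = np.concatenate([p[0] for p in parts])
        nb = np.concatenate([p[1] for p in parts])
        yb = np.concatenate([p[2] for p in parts])
        try:
            beta, _, _, converged, diag = _newton(Xb, nb, yb)
            if not converged or beta[i_dose] == 0:
                raise FitError(diag or "flat dose response")
            for pc in combos:
                shift = beta[i_chemo] * pc[1] if i_chemo is not None else 0.0
                draws[pc].append(float((logits[pc] - beta[0] - shift) / beta[i_dose]))
        except FitError:
            n_failed += 1
            continue
    n_converged = B - n_failed
    if n_converged < B / 2:
        raise FitError(
            f"block bootstrap unstable: {n_failed}/{B} replicates failed "
            "(separation or non-convergence)"
        )

    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    constraints = []
    for (p, c) in combos:
        vals = np.array(draws[(p, c)])
        constraints.append(
            DoseConstraint(
                target_rate=p,
                chemo=c,
                dose_ml=point[(p, c)],
                wald_ci=wald[(p, c)],
                bootstrap_ci=(
                    float(np.percentile(vals, lo_q)),
                    float(np.percentile(vals, hi_q)),
                ),
                n_replicates_requested=B,
                n_replicates_converged=n_converged,
                seed=seed,
            )
        )
    diag = BootstrapDiagnostics(
        n_requested=B, n_converged=n_converged, n_separated_or_failed=n_failed, seed=seed
    )
    return constraints, diag
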