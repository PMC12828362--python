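"""End-to-end analysis pipeline over the fixture or user-supplied data.

Stage order mirrors the analysis workflow the package implements:

1. median-split contingency tests of each candidate predictor;
2. univariable logistic screen (gate p < 0.2);
3. multivariable fit on the gated covariates;
4. leave-one-study-out CV comparing the dose-only and multivariable models;
5. inversion of the winning model to iso-risk dose constraints, with Wald
   and study-level block-bootstrap intervals;
6. decile calibration (and, when patient-level data exist, discrimination
   at the 5 % no-chemotherapy constraint).

Every stage logs unit counts in/out (complete-case filtering differs per
model spec, so the manifest makes the filtering auditable), and all outputs
are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .constraints import block_bootstrap_ci, invert_dose
from .evaluation import contingency_test, decile_calibration, threshold_validation
from .model import (
    FittedModel,
    ModelSpec,
    fit_logistic,
    loocv_by_cohort,
    screen_univariable,
    wald_p,
)
from .study_data import (
    CohortSummary,
    PatientRecord,
    builtin_fixture,
    median_split,
    read_cohorts,
    read_patients,
)

logger = logging.getLogger("oesotox.pipeline")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; the defaults are the published analysis settings:
    gate 0.2 for the univariable screen, two-sided 0.05 significance,
    iso-risk targets {5, 10, 20, 30} %, 2000 block-bootstrap replicates."""

    patients_path: str | None = None
    cohorts_path: str | None = None
    use_fixture: bool = False
    candidates: tuple[str, ...] = ("dose", "chemo", "interval")
    gate: float = 0.2
    alpha: float = 0.05
    target_rates: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30)
    bootstrap_B: int = 2000
    level: float = 0.95
    seed: int = 0
    output_dir: str = "results"
    cohort_chemo_coding: str = "fraction"


@dataclass
class PipelineResult:
    config: RunConfig
    contingency: pd.DataFrame
    screen: pd.DataFrame
    selected: tuple[str, ...]
    model: FittedModel
    cv_table: pd.DataFrame
    constraints: pd.DataFrame
    calibration: pd.DataFrame
    calibration_r: float
    calibration_p: float
    threshold: dict | None
    manifest: dict = field(default_factory=dict)


def _load_units(
    config: RunConfig,
) -> tuple[list[PatientRecord | CohortSummary], list[PatientRecord]]:
    """Returns (likelihood units, patient-level records for diagnostics)."""
    if config.use_fixture:
        fx = builtin_fixture()
        return list(fx.cohorts), fx.patients
    units: list[PatientRecord | CohortSummary] = []
    patients: list[PatientRecord] = []
    if config.patients_path:
        patients = read_patients(config.patients_path)
        units += patients
    if config.cohorts_path:
        units += read_cohorts(config.cohorts_path)
    if not units:
        raise StageError("load: no input data (set use_fixture or supply paths)")
    return units, patients


def _median_split_tests(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    outcomes = np.array([p.event for p in patients])
    for name, getter in (
        ("dose", lambda p: p.cdmax),
        ("chemo", lambda p: p.chemo),
        ("interval", lambda p: p.interval_months),
    ):
        values = [getter(p) for p in patients]
        if name == "chemo":
            mask = np.array([v is not None for v in values])
            labels = np.array([v for v, m in zip(values, mask) if m])
            median = np.nan
        else:
            split = median_split(values)
            mask = np.array([lab is not None for lab in split.labels])
            labels = np.array([lab for lab in split.labels if lab is not None])
            median = split.median
        res = contingency_test(labels, outcomes[mask])
        rows.append(
            {
                "variable": name,
                "split_at": median,
                "n_used": int(mask.sum()),
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute all stages; optionally persist CSV/JSON outputs.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    written before the failure are left on disk flagged in the manifest.
    """
    out = Path(config.output_dir)
    manifest: dict = {
        "seed": config.seed,
        "oesotox_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "status": "partial",
    }

    def persist(name: str, df: pd.DataFrame) -> None:
        if write:
            out.mkdir(parents=True, exist_ok=True)
            df.to_csv(out / name, index=False)

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        info = stage("load")
        units, patients = _load_units(config)
        info["n_units"] = len(units)
        info["n_patient_records"] = len(patients)

        info = stage("median_split_tests")
        contingency = (
            _median_split_tests(patients) if patients else pd.DataFrame()
        )
        persist("contingency.csv", contingency)

        info = stage("univariable_screen")
        screen = screen_univariable(
            units, config.candidates, config.gate, config.cohort_chemo_coding
        )
        info["selected"] = list(screen.selected)
        persist("screen.csv", screen.table)

        info = stage("multivariable_fit")
        ordered = tuple(c for c in ("dose", "chemo", "interval") if c in screen.selected)
        if "dose" not in ordered:
            raise StageError("multivariable_fit: dose did not pass the screen gate")
        mv_spec = ModelSpec(ordered, config.cohort_chemo_coding)
        model = fit_logistic(units, mv_spec)
        info["n_units"] = model.n_units
        info["n_dropped"] = model.n_dropped
        info["converged"] = model.converged
        if not model.converged:
            raise StageError(f"multivariable_fit: {model.diagnostic}")
        # covariates that lose significance alongside the others are dropped
        # before model comparison (dose, the variable of interest, is kept)
        retained = tuple(
            c
            for c in ordered
            if c == "dose" or wald_p(model, c) < config.alpha
        )
        if retained != ordered:
            info["dropped_at_multivariable"] = [c for c in ordered if c not in retained]
            mv_spec = ModelSpec(retained, config.cohort_chemo_coding)
            model = fit_logistic(units, mv_spec)
            info["n_units"] = model.n_units
            info["n_dropped"] = model.n_dropped

        info = stage("loocv")
        specs = [ModelSpec(("dose",), config.cohort_chemo_coding)]
        if mv_spec != specs[0]:
            specs.append(mv_spec)
        cv = loocv_by_cohort(units, specs)
        cv_table = pd.DataFrame(
            [
                {
                    "model": r.spec.label(),
                    "total_heldout_nll": r.total_score,
                    "n_folds": len(r.fold_scores),
                    "excluded_folds": ";".join(r.excluded_folds),
                }
                for r in cv
            ]
        )
        persist("cv_results.csv", cv_table)
        best_spec = cv[0].spec
        info["winner"] = best_spec.label()
        if best_spec != mv_spec:
            model = fit_logistic(units, best_spec)

        info = stage("dose_constraints")
        chemo_levels = (0, 1) if "chemo" in best_spec.covariates else (0,)
        constraint_rows, diag = block_bootstrap_ci(
            units,
            best_spec,
            config.target_rates,
            chemo_levels=chemo_levels,
            B=config.bootstrap_B,
            level=config.level,
            seed=config.seed,
        )
        constraints = pd.DataFrame(
            [
                {
                    "target_rate": c.target_rate,
                    "chemo": c.chemo,
                    "dose_ml_gy_eqd2": c.dose_ml,
                    "wald_lower": c.wald_ci[0],
                    "wald_upper": c.wald_ci[1],
                    "bootstrap_lower": c.bootstrap_ci[0],
                    "bootstrap_upper": c.bootstrap_ci[1],
                }
                for c in constraint_rows
            ]
        )
        persist("constraints.csv", constraints)
        info["bootstrap_converged"] = diag.n_converged
        info["bootstrap_failed"] = diag.n_separated_or_failed

        info = stage("calibration")
        bins, r, p = decile_calibration(model, units)
        calibration = pd.DataFrame(
            [
                {
                    "bin": b.bin_index,
                    "n": b.n_units,
                    "predicted_rate": b.predicted_rate,
                    "observed_rate": b.observed_rate,
                }
                for b in bins
            ]
        )
        persist("calibration.csv", calibration)
        info["pearson_r"] = r
        info["pearson_p"] = p

        threshold = None
        if patients and "chemo" in best_spec.covariates:
            cutoff = invert_dose(model, 0.05, chemo=0)
            t = threshold_validation(patients, cutoff)
            threshold = {
                "cutoff_gy_eqd2": cutoff,
                "rate_above": t.rate_above,
                "rate_below": t.rate_below,
                "n_above": t.n_above,
                "n_below": t.n_below,
            }
            manifest["stages"]["threshold"] = threshold

        manifest["model"] = {
            "covariates": list(best_spec.covariates),
            "coefficients": model.coefficients.tolist(),
            "covariance": model.covariance.tolist() if model.covariance is not None else None,
            "log_likelihood": model.log_likelihood,
            "n_units": model.n_units,
            "n_dropped": model.n_dropped,
            "wald_p": {c: wald_p(model, c) for c in best_spec.covariates},
            "data_hash": model.data_hash,
        }
        manifest["status"] = "complete"
    except StageError:
        raise
    except Exception as exc:  # annotate with the failing stage
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "load"
        raise StageError(f"{failed}: {exc}") from exc
    finally:
        if write:
            out.mkdir(parents=True, exist_ok=True)
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
            if manifest.get("model"):
                with open(out / "model.json", "w") as fh:
                    json.dump(manifest["model"], fh, indent=2)

    return PipelineResult(
        config=config,
        contingency=contingency,
        screen=screen.table,
        selected=screen.selected,
        model=model,
        cv_table=cv_table,
        constraints=constraints,
        calibration=calibration,
        calibration_r=r,
        calibration_p=p,
        threshold=threshold,
        manifest=manifest,
    )
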