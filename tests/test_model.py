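import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import kstest

from oesotox.model import (
    FitError,
    FittedModel,
    ModelSpec,
    fit_logistic,
    loocv_by_cohort,
    published_model,
    screen_univariable,
    units_frame,
    wald_p,
)
from oesotox.study_data import CohortSummary, PatientRecord
from oesotox.synthetic import SimulationDesign, simulate_patients


def _kernel_ll(b0, bd, doses, n, y):
    eta = b0 + bd * np.asarray(doses)
    return np.sum(y * eta - n * np.logaddexp(0.0, eta))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        cohort = CohortSummary("s", n=10, events=3, cdmax_rep=80.0, chemo_fraction=0.0)
        m = fit_logistic([cohort], ModelSpec(()))
        assert m.coef("intercept") == pytest.approx(logit(0.3), abs=1e-6)
        assert m.log_likelihood == pytest.approx(3 * np.log(0.3) + 7 * np.log(0.7))
        assert m.converged

    def test_mle_matches_brute_force_grid(self, toy_patients):
        """Newton optimum equals an independent likelihood grid search."""
        m = fit_logistic(toy_patients, ModelSpec(("dose",)))
        doses = np.array([p.cdmax for p in toy_patients])
        y = np.array([p.event for p in toy_patients], float)
        n = np.ones_like(y)

        # coarse-to-fine exhaustive search, final resolution 2.5e-4 / 2.5e-5
        b0s = np.arange(-15.0, 5.0, 0.1)
        bds = np.arange(-0.2, 0.3, 0.005)
        for _ in range(3):
            ll = np.array([[_kernel_ll(b0, bd, doses, n, y) for bd in bds] for b0 in b0s])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            best_b0, best_bd = b0s[i], bds[j]
            span0 = (b0s[1] - b0s[0]) * 2
            spand = (bds[1] - bds[0]) * 2
            b0s = np.linspace(best_b0 - span0, best_b0 + span0, 81)
            bds = np.linspace(best_bd - spand, best_bd + spand, 81)
        assert m.coef("intercept") == pytest.approx(best_b0, abs=1e-3)
        assert m.coef("dose") == pytest.approx(best_bd, abs=1e-3)

    def test_matches_statsmodels_glm(self):
        """Independent cross-check of coefficients and covariance on mixed data."""
        import statsmodels.api as sm

        patients = simulate_patients(
            SimulationDesign(n_studies=10, study_sizes=[40] * 10, seed=21)
        )
        cohorts = [
            CohortSummary("g1", n=50, events=9, cdmax_rep=100.0, chemo_fraction=0.4),
            CohortSummary("g2", n=30, events=2, cdmax_rep=60.0, chemo_fraction=0.1),
        ]
        data = patients + cohorts
        m = fit_logistic(data, ModelSpec(("dose", "chemo")))

        df = units_frame(data)
        X = np.column_stack([np.ones(len(df)), df["dose"], df["chemo"]])
        endog = np.column_stack([df["y"], df["n"] - df["y"]])
        ref = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(m.coefficients, ref.params, rtol=1e-6)
        np.testing.assert_allclose(m.covariance, ref.cov_params(), rtol=1e-4)

    def test_cohort_equals_expanded_patients(self):
        """A cohort of n identical patients gives the same fit as n records."""
        cohorts = [
            CohortSummary("a", n=7, events=2, cdmax_rep=60.0, chemo_fraction=0.0),
            CohortSummary("b", n=9, events=5, cdmax_rep=110.0, chemo_fraction=0.0),
        ]
        patients = [
            PatientRecord(f"{c.study_id}{i}", c.study_id, c.cdmax_rep, 0, None,
                          int(i < c.events),
                          "late" if i < c.events else "none")
            for c in cohorts
            for i in range(c.n)
        ]
        mc = fit_logistic(cohorts, ModelSpec(("dose",)))
        mp = fit_logistic(patients, ModelSpec(("dose",)))
        np.testing.assert_allclose(mc.coefficients, mp.coefficients, atol=1e-8)
        assert mc.log_likelihood == pytest.approx(mp.log_likelihood, abs=1e-8)

    def test_affine_dose_shift_reparameterizes_intercept_only(self, toy_patients):
        shift = 25.0
        m0 = fit_logistic(toy_patients, ModelSpec(("dose",)))
        shifted = [
            PatientRecord(p.patient_id, p.study_id, p.cdmax + shift, p.chemo,
                          p.interval_months, p.event, p.event_timing, p.event_grade)
            for p in toy_patients
        ]
        m1 = fit_logistic(shifted, ModelSpec(("dose",)))
        assert m1.coef("dose") == pytest.approx(m0.coef("dose"), abs=1e-6)
        assert m1.coef("intercept") == pytest.approx(
            m0.coef("intercept") - shift * m0.coef("dose"), abs=1e-4
        )

    def test_complete_separation_flagged_not_silent(self):
        patients = [
            PatientRecord(f"p{i}", "s", d, 0, None, int(d > 75),
                          "late" if d > 75 else "none")
            for i, d in enumerate([40, 50, 60, 70, 80, 90, 100, 110])
        ]
        m = fit_logistic(patients, ModelSpec(("dose",)))
        assert not m.converged
        assert "separation" in m.diagnostic
        with pytest.raises(FitError):
            wald_p(m, "dose")

    def test_all_events_or_no_events_is_error(self):
        all_events = [CohortSummary("s", 5, 5, 80.0, 0.0)]
        none = [CohortSummary("s", 5, 0, 80.0, 0.0)]
        for data in (all_events, none):
            with pytest.raises(FitError, match="no events|non-events"):
                fit_logistic(data, ModelSpec(("dose",)))

    def test_complete_case_dropping_counted(self, fixture_data):
        m = fit_logistic(fixture_data.cohorts, ModelSpec(("dose", "chemo")))
        assert m.n_units == 18
        assert m.n_dropped == 3  # three studies never recorded chemotherapy


class TestWald:
    def test_zero_coefficient_gives_p_one(self):
        m = FittedModel(
            spec=ModelSpec(("dose",)),
            coefficients=np.array([-2.0, 0.0]),
            covariance=np.diag([0.5, 0.01]),
            log_likelihood=-1.0,
            n_units=10,
        )
        assert wald_p(m, "dose") == pytest.approx(1.0)

    def test_coefficient_at_1p96_se_gives_p_05(self):
        m = FittedModel(
            spec=ModelSpec(("dose",)),
            coefficients=np.array([-2.0, 1.96 * 0.1]),
            covariance=np.diag([0.5, 0.01]),
            log_likelihood=-1.0,
            n_units=10,
        )
        assert wald_p(m, "dose") == pytest.approx(0.05, abs=1e-3)

    def test_absent_covariate_is_error(self):
        m = published_model()
        with pytest.raises(KeyError):
            m.coef("interval")

    def test_null_chemo_p_uniform_across_seeds(self):
        """Type-I sanity: with no true chemo effect, Wald p is ~ Uniform(0,1)."""
        ps = []
        for seed in range(120):
            design = SimulationDesign(
                n_studies=6,
                study_sizes=[100] * 6,
                true_beta=(-4.0, 0.03, 0.0),
                chemo_spike_none=0.0,
                chemo_spike_all=0.0,
                seed=300 + seed,
            )
            m = fit_logistic(simulate_patients(design), ModelSpec(("dose", "chemo")))
            if m.converged:
                ps.append(wald_p(m, "chemo"))
        assert len(ps) > 100
        assert kstest(ps, "uniform").pvalue > 0.01


class TestScreen:
    def test_strong_dose_null_interval(self):
        """Dose passes the 0.2 gate; an interval unrelated to outcome does not."""
        design = SimulationDesign(
            n_studies=12, study_sizes=[120] * 12, seed=17,
            chemo_spike_none=0.5, chemo_spike_all=0.2,
        )
        patients = simulate_patients(design)  # interval never enters the truth
        screen = screen_univariable(patients, ("dose", "interval"))
        assert "dose" in screen.selected
        assert "interval" not in screen.selected

    def test_gate_one_selects_all_fittable(self, toy_patients):
        screen = screen_univariable(toy_patients, ("dose", "chemo"), gate=1.0)
        assert set(screen.selected) == {"dose", "chemo"}

    def test_per_candidate_failure_does_not_abort(self):
        # chemo is constant -> singular fit; dose must still be screened
        patients = [
            PatientRecord(f"p{i}", "s", d, 0, None, e, "late" if e else "none")
            for i, (d, e) in enumerate(zip([40, 60, 80, 100, 55, 120], [0, 1, 0, 1, 0, 1]))
        ]
        screen = screen_univariable(patients, ("chemo", "dose"))
        row = screen.table.set_index("candidate")
        assert row.loc["chemo", "error"] != ""
        assert not np.isnan(row.loc["dose", "p"])


class TestLoocv:
    def test_two_identical_cohorts_intercept_only_hand_computation(self, two_cohorts):
        (result,) = loocv_by_cohort(two_cohorts, [ModelSpec(())])
        expected_fold = -(3 * np.log(0.3) + 7 * np.log(0.7))
        assert result.fold_scores["a"] == pytest.approx(expected_fold)
        assert result.fold_scores["b"] == pytest.approx(expected_fold)
        assert result.total_score == pytest.approx(sum(result.fold_scores.values()))

    def test_fewer_than_two_cohorts_is_error(self):
        cohort = CohortSummary("only", 10, 3, 80.0, 0.5)
        with pytest.raises(FitError):
            loocv_by_cohort([cohort], [ModelSpec(())])

    def test_pure_noise_covariate_does_not_improve_mean_heldout_score(self):
        """Expected held-out NLL of {dose, chemo} >= {dose} when chemo is null."""
        deltas = []
        for seed in range(60):
            design = SimulationDesign(
                n_studies=10, study_sizes=[30] * 10,
                true_beta=(-4.0, 0.03, 0.0),
                chemo_spike_none=0.0, chemo_spike_all=0.0,
                seed=700 + seed,
            )
            results = loocv_by_cohort(
                simulate_patients(design),
                [ModelSpec(("dose",)), ModelSpec(("dose", "chemo"))],
            )
            scores = {r.spec.covariates: r.total_score for r in results}
            deltas.append(scores[("dose", "chemo")] - scores[("dose",)])
        assert np.mean(deltas) > 0

    def test_real_chemo_effect_ranks_multivariable_first(self):
        design = SimulationDesign(
            n_studies=21, study_sizes=[95] * 21, seed=77,
            chemo_spike_none=0.4, chemo_spike_all=0.2,
        )
        results = loocv_by_cohort(
            simulate_patients(design),
            [ModelSpec(("dose",)), ModelSpec(("dose", "chemo"))],
        )
        assert results[0].spec.covariates == ("dose", "chemo")
        assert results[0].total_score < results[1].total_score
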