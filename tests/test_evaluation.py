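import math

import numpy as np
import pytest

from oesotox.evaluation import (
    contingency_test,
    decile_calibration,
    threshold_validation,
)
from oesotox.model import FittedModel, ModelSpec, fit_logistic, published_model
from oesotox.study_data import CohortSummary, PatientRecord
from oesotox.synthetic import SimulationDesign, simulate_patients


def fisher_p_enumeration(table):
    """Independent oracle: two-sided Fisher p by hypergeometric enumeration.

    Enumerates every 2x2 table with the observed margins and sums the
    probabilities of tables no more probable than the observed one.
    """
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (
            math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(n, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestDecileCalibration:
    def test_perfectly_calibrated_data_gives_r_one(self):
        """Cohorts whose observed rates equal the model's predictions."""
        model = published_model()
        cohorts = []
        for i, dose in enumerate(np.linspace(40, 160, 20)):
            p = model.predict(dose=dose, chemo=0)
            n = 1000
            cohorts.append(
                CohortSummary(f"s{i}", n=n, events=round(n * p), cdmax_rep=float(dose),
                              chemo_fraction=0.0)
            )
        bins, r, p_val = decile_calibration(model, cohorts)
        assert r > 0.999
        assert p_val < 1e-6

    def test_bins_conserve_units_and_events(self):
        patients = simulate_patients(
            SimulationDesign(n_studies=10, study_sizes=[50] * 10, seed=41,
                             chemo_spike_none=0.4, chemo_spike_all=0.2)
        )
        model = fit_logistic(patients, ModelSpec(("dose", "chemo")))
        bins, _, _ = decile_calibration(model, patients)
        assert len(bins) == 10
        assert sum(b.n_units for b in bins) == len(patients)
        total_events = sum(b.observed_rate * b.n_units for b in bins)
        assert total_events == pytest.approx(sum(p.event for p in patients))
        # remainder spread over the lowest bins: sizes differ by at most 1
        sizes = [b.n_units for b in bins]
        assert max(sizes) - min(sizes) <= 1

    def test_equal_count_binning_is_deterministic_under_ties(self):
        # grouped units share predictions; repeated runs must bin identically
        cohorts = [
            CohortSummary(f"s{i}", n=20, events=2, cdmax_rep=80.0, chemo_fraction=0.0)
            for i in range(12)
        ] + [
            CohortSummary("hi", n=20, events=8, cdmax_rep=150.0, chemo_fraction=0.0)
        ]
        model = published_model()
        a = decile_calibration(model, cohorts)
        b = decile_calibration(model, cohorts)
        assert a[0] == b[0]

    def test_flat_predictions_raise_degenerate_binning(self):
        model = FittedModel(
            spec=ModelSpec(()),
            coefficients=np.array([-2.0]),
            covariance=None,
            log_likelihood=None,
            n_units=0,
        )
        patients = [
            PatientRecord(f"p{i}", "s", 80.0, 0, None, i % 2,
                          "late" if i % 2 else "none")
            for i in range(20)
        ]
        with pytest.raises(ValueError, match="identical"):
            decile_calibration(model, patients)

    def test_well_specified_model_calibrates_on_large_synthetic_data(self):
        """r > 0.9 in nearly all replicates when the model family is true."""
        good = 0
        n_seeds = 25
        for seed in range(n_seeds):
            patients = simulate_patients(
                SimulationDesign(n_studies=10, study_sizes=[500] * 10,
                                 seed=900 + seed,
                                 chemo_spike_none=0.4, chemo_spike_all=0.2)
            )
            model = fit_logistic(patients, ModelSpec(("dose", "chemo")))
            _, r, _ = decile_calibration(model, patients)
            good += r > 0.9
        assert good >= 0.9 * n_seeds


class TestThresholdValidation:
    def _patients(self, pairs):
        return [
            PatientRecord(f"p{i}", "s", d, 0, None, e, "late" if e else "none")
            for i, (d, e) in enumerate(pairs)
        ]

    def test_toy_hand_count(self):
        res = threshold_validation(
            self._patients([(50, 0), (60, 0), (100, 1), (120, 0)]), cutoff=94.2
        )
        assert res.rate_above == pytest.approx(0.5)
        assert res.rate_below == pytest.approx(0.0)
        assert res.n_above + res.n_below == 4

    def test_empty_group_rate_is_undefined_not_zero(self):
        res = threshold_validation(self._patients([(50, 1), (60, 0)]), cutoff=94.2)
        assert res.rate_above is None
        assert res.rate_below == pytest.approx(0.5)

    def test_cutoff_above_max_dose_reproduces_all_below(self):
        patients = self._patients([(50, 0), (60, 1), (100, 1)])
        res = threshold_validation(patients, cutoff=1000.0)
        assert res.n_above == 0
        assert res.rate_below == pytest.approx(2 / 3)


class TestContingency:
    def test_perfect_independence_chi_squared(self):
        labels = ["a"] * 10 + ["b"] * 10
        outcomes = ([0] * 5 + [1] * 5) * 2
        res = contingency_test(labels, outcomes)
        assert res.test == "chi_squared"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_doubling_cells_preserves_independence_p(self):
        labels = ["a"] * 20 + ["b"] * 20
        outcomes = ([0] * 10 + [1] * 10) * 2
        res = contingency_test(labels, outcomes)
        assert res.p_value == pytest.approx(1.0)

    def test_small_expected_counts_switch_to_fisher(self):
        labels = ["a"] * 10 + ["b"] * 10
        outcomes = [0] * 9 + [1] + [1] * 8 + [0] * 2
        res = contingency_test(labels, outcomes)
        assert res.test == "fisher_exact"
        assert res.statistic is None

    @pytest.mark.parametrize(
        "table",
        [
            [[1, 9], [8, 2]],
            [[2, 3], [4, 1]],
            [[0, 7], [5, 5]],
            [[3, 3], [3, 3]],
            [[6, 2], [1, 8]],
        ],
    )
    def test_fisher_matches_hypergeometric_enumeration(self, table):
        labels = (["a"] * (table[0][0] + table[0][1])) + (
            ["b"] * (table[1][0] + table[1][1])
        )
        outcomes = (
            [0] * table[0][0] + [1] * table[0][1] + [0] * table[1][0] + [1] * table[1][1]
        )
        res = contingency_test(labels, outcomes)
        assert res.test == "fisher_exact"
        assert res.p_value == pytest.approx(fisher_p_enumeration(table), abs=1e-10)

    def test_zero_margin_returns_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = contingency_test(["a", "a", "b", "b"], [0, 0, 0, 0])
        assert res.p_value == 1.0
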