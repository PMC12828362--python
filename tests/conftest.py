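import pytest

from oesotox.study_data import CohortSummary, PatientRecord, builtin_fixture


@pytest.fixture(scope="session")
def fixture_data():
    return builtin_fixture()


@pytest.fixture
def toy_patients():
    """Six patients with a clear positive dose effect, no separation."""
    doses = [40, 55, 70, 90, 110, 130]
    events = [0, 0, 1, 0, 1, 1]
    return [
        PatientRecord(
            patient_id=f"p{i}",
            study_id=f"s{i % 3}",
            cdmax=d,
            chemo=i % 2,
            interval_months=12.0,
            event=e,
            event_timing="late" if e else "none",
            event_grade=3 if e else None,
        )
        for i, (d, e) in enumerate(zip(doses, events))
    ]


@pytest.fixture
def two_cohorts():
    return [
        CohortSummary(study_id="a", n=10, events=3, cdmax_rep=80.0, chemo_fraction=0.5),
        CohortSummary(study_id="b", n=10, events=3, cdmax_rep=80.0, chemo_fraction=0.5),
    ]
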