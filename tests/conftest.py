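import pytest

from cohortwatch.synthetic_emr import worked_fixture, worked_fixture_config


@pytest.fixture
def fixture_tables():
    return worked_fixture()


@pytest.fixture
def fixture_config():
    return worked_fixture_config()


# Hand-traced attrition oracle for the worked fixture (committed alongside the
# fixture; see synthetic_emr.worked_fixture for the per-patient trace).
FIXTURE_ATTRITION = [
    ("all patients", 12, 0, 12),
    ("exposure prescription within study window", 12, 1, 11),  # P10
    ("no prior exposure within washout", 11, 2, 9),  # P04, P12
    ("single exposure group on index date", 9, 1, 8),  # P05
    ("aged at least 20 years", 8, 1, 7),  # P06
    ("no cancer in prior year", 7, 1, 6),  # P07
    ("no prior stroke within 365 days", 6, 1, 5),  # P08
    ("no prior ich within 365 days", 6, 0, 6),
]

# Hand-traced ITT/AT follow-up oracle: patient -> (mode -> (time, event, reason))
FIXTURE_FOLLOWUP = {
    "P01": {"ITT": (730, 0, "max_followup"), "AT": (30, 0, "discontinuation")},
    "P02": {"ITT": (730, 0, "max_followup"), "AT": (90, 0, "discontinuation")},
    "P03": {"ITT": (100, 1, "outcome"), "AT": (30, 0, "discontinuation")},
    "P09": {"ITT": (400, 0, "data_end"), "AT": (400, 0, "data_end")},
    "P11": {"ITT": (50, 1, "outcome"), "AT": (50, 1, "outcome")},
}
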