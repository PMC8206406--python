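import numpy as np
import pandas as pd
import pytest

import cohortperm as cp


def make_dataset(members: list[tuple], enrollment: list[tuple],
                 events: list[tuple]) -> cp.ClaimsDataset:
    """Build a ClaimsDataset from row tuples.

    members: (member_id, sex, birth_year); enrollment: (member_id, start, end);
    events: (member_id, date, kind, system, code[, value]).
    """
    mem = pd.DataFrame(members, columns=["member_id", "sex", "birth_year"])
    enr = pd.DataFrame(enrollment, columns=["member_id", "start", "end"])
    for col in ("start", "end"):
        enr[col] = pd.to_datetime(enr[col])
    rows = [e if len(e) == 6 else (*e, np.nan) for e in events]
    ev = pd.DataFrame(rows, columns=["member_id", "date", "kind", "system",
                                     "code", "value"])
    ev["date"] = pd.to_datetime(ev["date"])
    ev["value"] = ev["value"].astype(float)
    return cp.ClaimsDataset(mem, enr, ev)


SPAN = ("2010-01-01", "2014-12-31")   # window = 2010-01-01 .. 2013-12-31


@pytest.fixture(scope="session")
def toy_dataset() -> cp.ClaimsDataset:
    """Ten hand-built members exercising every branch of the rule trees."""
    members = [
        ("C1", "male", 1950),    # case: T2D dx + med
        ("T1", "female", 1980),  # type 1 only: excluded everywhere
        ("N1", "female", 1960),  # normal glucose value
        ("N2", "male", 1955),    # no labs at all
        ("N3", "female", 1948),  # order without returned value
        ("N4", "male", 1970),    # abnormal (non-normal) glucose value, no T2D dx
        ("F1", "female", 1952),  # family-history code
        ("D1", "male", 1949),    # case via abnormal HbA1c; depressed
        ("D2", "female", 1961),  # depression dx outside the window
        ("V1", "male", 1990),    # single claim: below the visit minimum
    ]
    enrollment = [(m[0], *SPAN) for m in members]
    events = [
        ("C1", "2010-06-01", "diagnosis", "ICD9", "250.00"),
        ("C1", "2010-07-01", "pharmacy", "NDC", "60000000101"),
        ("T1", "2010-05-01", "diagnosis", "ICD9", "250.01"),
        ("T1", "2010-06-01", "pharmacy", "NDC", "60000000201"),
        ("N1", "2010-02-01", "diagnosis", "ICD9", "401.9"),
        ("N1", "2011-03-01", "diagnosis", "ICD9", "465.9"),
        ("N1", "2011-05-05", "lab_result", "LOINC", "2339-0", 100.0),
        ("N2", "2010-03-01", "diagnosis", "ICD9", "401.9"),
        ("N2", "2012-01-10", "diagnosis", "ICD9", "401.9"),
        ("N3", "2010-04-01", "diagnosis", "ICD9", "724.2"),
        ("N3", "2011-04-02", "diagnosis", "ICD9", "530.81"),
        ("N3", "2011-06-01", "procedure", "CPT", "82947"),
        ("N4", "2010-02-02", "diagnosis", "ICD9", "401.9"),
        ("N4", "2010-09-09", "diagnosis", "ICD9", "272.4"),
        ("N4", "2012-03-03", "lab_result", "LOINC", "2339-0", 250.0),
        ("F1", "2010-01-15", "diagnosis", "ICD9", "V18.0"),
        ("F1", "2010-02-15", "diagnosis", "ICD9", "401.9"),
        ("F1", "2011-01-01", "diagnosis", "ICD9", "465.9"),
        ("F1", "2011-02-02", "lab_result", "LOINC", "2345-7", 95.0),
        ("D1", "2010-03-03", "diagnosis", "ICD9", "250.02"),
        ("D1", "2010-04-04", "lab_result", "LOINC", "4548-4", 8.2),
        ("D1", "2011-01-01", "diagnosis", "ICD9", "311"),
        ("D1", "2011-02-01", "diagnosis", "ICD9", "401.9"),
        ("D2", "2010-05-05", "diagnosis", "ICD9", "401.9"),
        ("D2", "2011-06-06", "diagnosis", "ICD9", "272.4"),
        ("D2", "2014-06-01", "diagnosis", "ICD9", "311"),
        ("V1", "2010-08-08", "diagnosis", "ICD9", "401.9"),
    ]
    return make_dataset(members, enrollment, events)


@pytest.fixture(scope="session")
def toy_cohorts(toy_dataset) -> dict[str, pd.DataFrame]:
    return cp.build_cohorts(toy_dataset, cp.PhenotypeConfig())


@pytest.fixture(scope="session")
def generated():
    """A moderately sized default-configuration dataset plus latent truth."""
    cfg = cp.SyntheticConfig(n_members=8000, seed=42)
    ds, truth = cp.generate(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def generated_cohorts(generated):
    _, ds, _ = generated
    return cp.build_cohorts(ds, cp.PhenotypeConfig())
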