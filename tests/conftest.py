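import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ckdval.synthetic import CohortParams, RawEhrBundle, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


PATIENT_COLUMNS = ["id", "birth_date", "sex", "ethnicity", "deprivation",
                   "death_date", "moveout_date"]


def make_bundle(patients=(), labs=(), codes=(), prescriptions=(),
                entry_start="2009-04-01", entry_end="2010-03-31",
                study_end="2014-12-31") -> RawEhrBundle:
    """Hand-build a tiny bundle from row dicts (dates as strings)."""
    pat = pd.DataFrame(list(patients), columns=PATIENT_COLUMNS)
    for col in ("birth_date", "death_date", "moveout_date"):
        pat[col] = pd.to_datetime(pat[col]) if len(pat) else pd.Series(dtype="datetime64[ns]")
    lab = pd.DataFrame(list(labs), columns=["id", "date", "analyte", "value"])
    code = pd.DataFrame(list(codes), columns=["id", "date", "code_class"])
    rx = pd.DataFrame(list(prescriptions), columns=["id", "date", "drug_class"])
    for frame in (lab, code, rx):
        frame["date"] = pd.to_datetime(frame["date"]) if len(frame) else pd.Series(dtype="datetime64[ns]")
    return RawEhrBundle(
        patients=pat, labs=lab, codes=code, prescriptions=rx,
        truth=pd.DataFrame(),
        entry_start=pd.Timestamp(entry_start),
        entry_end=pd.Timestamp(entry_end),
        study_end=pd.Timestamp(study_end),
    )


def patient(pid, birth="1960-01-01", sex="M", ethnicity="white",
            deprivation=1.0, death=None, moveout=None):
    return {
        "id": pid, "birth_date": birth, "sex": sex, "ethnicity": ethnicity,
        "deprivation": deprivation, "death_date": death, "moveout_date": moveout,
    }


@pytest.fixture(scope="session")
def small_bundle():
    """A 600-patient synthetic bundle shared across tests."""
    return generate_cohort(CohortParams(n_patients=600, seed=11))


@pytest.fixture(scope="session")
def large_bundle():
    """A 20,000-patient bundle for sampling-tolerance checks."""
    return generate_cohort(CohortParams(n_patients=20000, seed=5))
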