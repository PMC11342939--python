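import numpy as np
import pandas as pd
import pytest

from vplung.cohort import PatientRecord
from vplung.preprocessing import (
    EligiblePatient,
    detect_suspected_onset,
    extract_windows,
    raw_features,
)


def make_record(
    patient_id: str = "p1",
    hospital_id: str = "H1",
    age_bin: str = "18-65",
    height_bin: str = "<170cm",
    weight_bin: str = "<80kg",
    bmi_bin: str = "18-25",
    icd_codes=None,
    mv_hours: float = 100.0,
    observations: pd.DataFrame = None,
) -> PatientRecord:
    """Minimal patient record for rule-level tests."""
    if observations is None:
        observations = pd.DataFrame(
            columns=["time_h", "variable", "value"])
    return PatientRecord(
        patient_id=patient_id, hospital_id=hospital_id, age_bin=age_bin,
        height_bin=height_bin, weight_bin=weight_bin, bmi_bin=bmi_bin,
        icd_codes=icd_codes or [], mv_hours=mv_hours,
        observations=observations)


def obs_frame(rows):
    """rows: iterable of (time_h, variable, value)."""
    return pd.DataFrame(rows, columns=["time_h", "variable", "value"])


def build_eligible(records):
    """Onset detection + window extraction, skipping the population-level
    filters (inclusion, k-anonymity) that are irrelevant to per-patient
    matching experiments."""
    out = []
    for r in records:
        try:
            t0 = detect_suspected_onset(r)
        except Exception:
            continue
        if t0 is None:
            continue
        try:
            wp, sl = extract_windows(r, t0)
            f = raw_features(r.patient_id, sl)
        except Exception:
            continue
        out.append(EligiblePatient(record=r, windows=wp, slices=sl,
                                   features=f))
    return out


@pytest.fixture(scope="session")
def default_cohort_200():
    """One default 200-patient cohort, shared across read-only tests."""
    from vplung.cohort import default_hospitals, generate_cohort
    records, truths = generate_cohort(default_hospitals(200), seed=1)
    return records, truths
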