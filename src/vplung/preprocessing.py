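"""Cohort preprocessing: inclusion, k-anonymity, onset detection, windows.

Implements the operational definitions used to assemble the analysis
cohort: adult patients with >= 24 h of invasive ventilation, the
k-anonymity exclusion rule applied to binned biometrics, the suspected
ARDS onset (first time the P/F ratio drops below 300 mmHg and stays
below for at least 24 h), the two analysis windows around the onset
(w1 = [t0-48h, t0-24h), w2 = [t0, t0+24h), the day in between treated as
transient and excluded), and per-window mean raw features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import CHARTED_VARIABLES, PatientRecord

__all__ = [
    "WindowPair",
    "RawFeatureVector",
    "EligiblePatient",
    "PreprocessResult",
    "InsufficientDataError",
    "WindowUnderflowError",
    "IneligibleError",
    "PF_THRESHOLD",
    "apply_inclusion_criteria",
    "k_anonymity_filter",
    "detect_suspected_onset",
    "extract_windows",
    "raw_features",
    "preprocess_cohort",
]

log = logging.getLogger(__name__)

PF_THRESHOLD = 300.0       # mmHg, impaired-oxygenation threshold
SUSTAIN_HOURS = 24.0       # the drop must persist at least this long
MAX_LOCF_GAP_HOURS = 12.0  # charting gaps longer than this break sustainment
MIN_MV_HOURS = 24.0
BINNED_VARS = ("age_bin", "height_bin", "weight_bin", "bmi_bin")
ADULT_AGE_BINS = {"18-65", "65+"}

RAW_VARIABLES = CHARTED_VARIABLES  # the 10 charted variables, 2 windows each


class InsufficientDataError(ValueError):
    pass


class WindowUnderflowError(ValueError):
    pass


class IneligibleError(ValueError):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class WindowPair:
    """Half-open analysis windows around the suspected onset t0."""

    t0: float

    @property
    def w1(self) -> Tuple[float, float]:
        return (self.t0 - 48.0, self.t0 - 24.0)

    @property
    def w2(self) -> Tuple[float, float]:
        return (self.t0, self.t0 + 24.0)


@dataclass(frozen=True)
class RawFeatureVector:
    patient_id: str
    values: Dict[str, float]  # "variable@w1" / "variable@w2" -> window mean


@dataclass
class EligiblePatient:
    record: PatientRecord
    windows: WindowPair
    slices: Dict[str, pd.DataFrame]  # "w1"/"w2": wide frames (time x variable)
    features: RawFeatureVector


@dataclass
class PreprocessResult:
    eligible: List[EligiblePatient]
    exclusions: pd.DataFrame  # patient_id, rule, detail


def apply_inclusion_criteria(
    records: Sequence[PatientRecord],
) -> List[PatientRecord]:
    """Adult age bin and cumulative invasive ventilation of >= 24 h."""
    kept = []
    for r in records:
        if r.mv_hours is None or (isinstance(r.mv_hours, float)
                                  and np.isnan(r.mv_hours)):
            log.warning("patient %s skipped: missing mv_hours", r.patient_id)
            continue
        if r.age_bin in ADULT_AGE_BINS and r.mv_hours >= MIN_MV_HOURS:
            kept.append(r)
    return kept


def k_anonymity_filter(
    records: Sequence[PatientRecord],
    binned_vars: Sequence[str] = BINNED_VARS,
    min_interval: int = 8,
    min_combination: int = 10,
) -> Tuple[List[PatientRecord], pd.DataFrame]:
    """Privacy-driven exclusion on binned biometrics.

    A patient is excluded when any of their intervals holds fewer than
    ``min_interval`` patients (the whole interval is suppressed), or when
    their own cell of the full cross-classification holds fewer than
    ``min_combination``.  All counts come from a single pass over the
    original table; exclusions are the union of both rules.  Empty cells
    pose no re-identification risk and are ignored.
    """
    if not records:
        return [], pd.DataFrame(columns=["patient_id", "rule", "detail"])
    df = pd.DataFrame(
        [{v: getattr(r, v) for v in binned_vars} for r in records])
    cells = df.groupby(list(binned_vars), observed=True).size()
    interval_counts = {var: df[var].value_counts() for var in binned_vars}
    excl_rows = []
    excluded_ids = set()

    def exclude(r, detail):
        if r.patient_id not in excluded_ids:
            excluded_ids.add(r.patient_id)
            excl_rows.append({"patient_id": r.patient_id,
                              "rule": "k_anonymity", "detail": detail})

    for r in records:
        for var in binned_vars:
            c = int(interval_counts[var][getattr(r, var)])
            if c < min_interval:
                exclude(r, f"{var}={getattr(r, var)}: interval count "
                           f"{c} < {min_interval}")
        cell = tuple(getattr(r, v) for v in binned_vars)
        cc = int(cells[cell])
        if cc < min_combination:
            exclude(r, f"combination cell {cell} has {cc} < "
                       f"{min_combination}")
    retained = [r for r in records if r.patient_id not in excluded_ids]
    return retained, pd.DataFrame(
        excl_rows, columns=["patient_id", "rule", "detail"])


def _pf_series(record_or_df) -> pd.DataFrame:
    """Rowwise P/F ratio table (time_h, pf) from long observations."""
    obs = (record_or_df.observations
           if isinstance(record_or_df, PatientRecord) else record_or_df)
    wide = obs.pivot_table(index="time_h", columns="variable", values="value")
    if "pao2" not in wide or "fio2" not in wide:
        raise InsufficientDataError("PaO2/FiO2 observations required")
    pf = (wide["pao2"] / wide["fio2"]).dropna()
    return pf


def detect_suspected_onset(record_or_df) -> Optional[float]:
    """First time the charted P/F drops below 300 mmHg for >= 24 h.

    Sustainment is judged on charted rows with last observation carried
    forward between rows; a charting gap longer than 12 h breaks the run.
    Returns None when no qualifying drop exists.
    """
    pf = _pf_series(record_or_df)
    if len(pf) < 2:
        raise InsufficientDataError("need at least 2 charted P/F rows")
    times = pf.index.to_numpy(dtype=float)
    vals = pf.to_numpy(dtype=float)
    n = len(vals)
    for i in range(n):
        if vals[i] >= PF_THRESHOLD:
            continue
        t_start = times[i]
        t_end = t_start
        ok = True
        for j in range(i + 1, n):
            if times[j] - t_end > MAX_LOCF_GAP_HOURS:
                break  # run of valid LOCF coverage ends here
            if vals[j] >= PF_THRESHOLD:
                if times[j] <= t_start + SUSTAIN_HOURS:
                    ok = False
                break
            t_end = times[j]
            if t_end >= t_start + SUSTAIN_HOURS:
                break
        if ok and t_end - t_start >= SUSTAIN_HOURS:
            return float(t_start)
    return None


def extract_windows(
    record: PatientRecord, t0: float
) -> Tuple[WindowPair, Dict[str, pd.DataFrame]]:
    """Slice the charted series into the two half-open analysis windows."""
    if t0 < 48.0:
        raise WindowUnderflowError(
            f"t0={t0}h leaves no room for the pre-onset window")
    wp = WindowPair(t0)
    wide = record.observations.pivot_table(
        index="time_h", columns="variable", values="value").sort_index()
    slices = {}
    for name, (lo, hi) in (("w1", wp.w1), ("w2", wp.w2)):
        sl = wide[(wide.index >= lo) & (wide.index < hi)]
        bga_ok = (not sl.empty and
                  all(v in sl and sl[v].notna().any()
                      for v in ("pao2", "paco2", "ph", "sao2", "fio2")))
        if not bga_ok:
            raise IneligibleError(f"no_bga_in_{name}")
        slices[name] = sl
    return wp, slices


def raw_features(
    patient_id: str, slices: Dict[str, pd.DataFrame]
) -> RawFeatureVector:
    """Per-window arithmetic means of the 10 charted variables (20 values)."""
    values: Dict[str, float] = {}
    for wname in ("w1", "w2"):
        sl = slices[wname]
        for var in RAW_VARIABLES:
            if var not in sl or not sl[var].notna().any():
                raise IneligibleError(f"missing_{var}_in_{wname}")
            values[f"{var}@{wname}"] = float(sl[var].mean())
    return RawFeatureVector(patient_id=patient_id, values=values)


def preprocess_cohort(records: Sequence[PatientRecord]) -> PreprocessResult:
    """Full preprocessing pass: inclusion -> k-anonymity -> onset/windows."""
    excl_rows: List[dict] = []
    included = apply_inclusion_criteria(records)
    inc_ids = {r.patient_id for r in included}
    for r in records:
        if r.patient_id not in inc_ids:
            excl_rows.append({"patient_id": r.patient_id,
                              "rule": "inclusion_criteria",
                              "detail": f"age_bin={r.age_bin}, "
                                        f"mv_hours={r.mv_hours}"})
    anon, anon_excl = k_anonymity_filter(included)
    excl_rows.extend(anon_excl.to_dict("records"))
    eligible: List[EligiblePatient] = []
    for r in anon:
        try:
            t0 = detect_suspected_onset(r)
        except InsufficientDataError as e:
            excl_rows.append({"patient_id": r.patient_id,
                              "rule": "insufficient_data", "detail": str(e)})
            continue
        if t0 is None:
            excl_rows.append({"patient_id": r.patient_id,
                              "rule": "no_suspected_onset", "detail": ""})
            continue
        try:
            wp, slices = extract_windows(r, t0)
            feats = raw_features(r.patient_id, slices)
        except (WindowUnderflowError, IneligibleError) as e:
            excl_rows.append({"patient_id": r.patient_id,
                              "rule": "window_eligibility", "detail": str(e)})
            continue
        eligible.append(EligiblePatient(
            record=r, windows=wp, slices=slices, features=feats))
    return PreprocessResult(
        eligible=eligible,
        exclusions=pd.DataFrame(
            excl_rows, columns=["patient_id", "rule", "detail"]))
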