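"""Synthetic multi-hospital ICU cohort generation with known ground truth.

Real multi-center ICU extracts cannot be redistributed, so every
downstream stage of the pipeline is exercised on generated cohorts that
emulate their structure: per-patient charted time series (blood gases and
ventilator settings), binned biometrics, ICD-10 codes, hospital-specific
charting conventions and analyzer offsets, latent disease archetypes, and
under-diagnosis of ARDS (only a fraction of true-ARDS patients carry the
J80 code).

Each patient is a latent virtual-patient configuration; charted blood
gases are produced by running the gas-exchange simulator at every
charting time, after which hospital measurement effects and i.i.d.
Gaussian noise are applied.  Deterioration (the archetype-specific event
at the suspected-onset time t0) completes within the last charting step
before t0, so the charted P/F ratio crosses the 300 mmHg threshold at t0
itself and the operational onset definition can recover the ground
truth; the 24 h before t0 are still treated as transient and excluded by
the analysis windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .gas_exchange import VPConfiguration, VentilatorInputs, simulate_steady_state

__all__ = [
    "ARCHETYPES",
    "BGA_VARIABLES",
    "CHARTED_VARIABLES",
    "HospitalProfile",
    "NoiseModel",
    "GroundTruthPatient",
    "PatientRecord",
    "archetype_defaults",
    "default_hospitals",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

ARCHETYPES = ("ards", "cardiac", "copd_like", "control")

BGA_VARIABLES = ("pao2", "paco2", "ph", "sao2", "fio2")
CHARTED_VARIABLES = BGA_VARIABLES + ("peep", "vt", "rr", "pinsp", "hr")

AGE_BINS = ("18-65", "65+")
HEIGHT_BINS = ("<170cm", "170cm+")
WEIGHT_BINS = ("<80kg", "80kg+")
# BMI bin is a deterministic function of the height/weight bins, mirroring
# how binned biometrics are redundant in de-identified extracts.
_BMI_MAP = {
    ("<170cm", "<80kg"): "18-25",
    ("<170cm", "80kg+"): "30+",
    ("170cm+", "<80kg"): "18-25",
    ("170cm+", "80kg+"): "25-30",
}
_WEIGHT_KG = {"<80kg": 70.0, "80kg+": 90.0}

SETTINGS_BLOCK_HOURS = 8.0  # ventilator settings are re-charted per 8h block


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class HospitalProfile:
    """Systematic conventions of one contributing hospital."""

    hospital_id: str
    n_patients: int
    pao2_bias: float = 0.0          # additive blood-gas analyzer offset, mmHg
    peep_policy_offset: float = 0.0  # additive PEEP policy offset, cmH2O
    fio2_rounding: float = 0.05      # charting grid step for FiO2 (0 = exact)
    charting_interval: float = 4.0   # hours between charted rows
    vt_per_kg_policy: float = 7.0    # tidal volume setpoint, mL/kg
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {a: 0.25 for a in ARCHETYPES})

    def __post_init__(self) -> None:
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise CohortConfigError(
                f"archetype prevalences must sum to 1, got {total}")
        if not self.archetype_mix:
            raise CohortConfigError("archetype mix must not be empty")
        if self.charting_interval <= 0:
            raise CohortConfigError("charting_interval must be positive")

    def zero_effects(self) -> "HospitalProfile":
        """Copy with all measurement-layer effects removed (audit control)."""
        return dataclasses.replace(
            self, pao2_bias=0.0, peep_policy_offset=0.0, fio2_rounding=0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise (analyzer repeatability)."""

    pao2: float = 5.0    # mmHg
    paco2: float = 2.0   # mmHg
    ph: float = 0.02
    sao2: float = 0.01   # fraction
    pinsp: float = 1.0   # cmH2O

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroundTruthPatient:
    patient_id: str
    hospital_id: str
    archetype: str
    true_config_w1: VPConfiguration
    true_ncc_w2: int
    diagnosed_ards: bool
    t0: float  # suspected-onset time, hours from admission
    sv_multiplier_w2: float = 1.0  # cardiac decompensation (generator detail)

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise CohortConfigError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "ards" and not (
                self.true_ncc_w2 > self.true_config_w1.n_cc):
            raise CohortConfigError("ARDS ground truth requires ncc_w2 > ncc_w1")
        if self.diagnosed_ards and self.archetype != "ards":
            raise CohortConfigError("only true ARDS can carry the diagnosis")


@dataclass
class PatientRecord:
    patient_id: str
    hospital_id: str
    age_bin: str
    height_bin: str
    weight_bin: str
    bmi_bin: str
    icd_codes: List[str]
    mv_hours: float
    observations: pd.DataFrame  # columns: time_h, variable, value


def archetype_defaults() -> Dict[str, dict]:
    """Default latent-parameter library per disease archetype.

    Values are sampling ranges; ``("uniform", lo, hi)`` draws a float,
    ``("randint", lo, hi)`` an integer in [lo, hi].  n_cc entries are
    expressed per 100 compartments and scaled to the working compartment
    count.  The base entry is the mid-range (control) physiology; each
    archetype overrides the parameters that define it:

    * ards: moderate anatomical shunt, large increase in closed
      compartments at onset (atelectasis / alveolar flooding);
    * cardiac: low stroke volume with compensatory tachycardia and a
      further stroke-volume drop at onset, closed compartments unchanged;
    * copd_like: enlarged dead space and strong flow-resistance
      heterogeneity, moderate closed-compartment increase (mucus
      plugging) at onset;
    * control: mid-range physiology with a moderate non-ARDS
      deterioration (e.g. post-operative atelectasis) at onset.
    """
    base = {
        "fs_anat": ("uniform", 0.02, 0.06),
        "rq": ("uniform", 0.75, 0.95),
        "vd": ("uniform", 0.12, 0.18),
        "vo2": ("uniform", 180.0, 250.0),
        "sv": ("uniform", 70.0, 100.0),
        "ie": ("uniform", 0.4, 0.8),
        "mu_fr": ("uniform", -0.3, 0.3),
        "sigma_fr": ("uniform", 0.1, 0.4),
        "mu_vr": ("uniform", -0.3, 0.3),
        "sigma_vr": ("uniform", 0.1, 0.4),
        "hr": ("uniform", 72.0, 96.0),
        "ncc_w1_per100": ("randint", 0, 5),
        "delta_ncc_per100": None,     # archetype-specific
        "sv_multiplier_w2": ("uniform", 1.0, 1.0),
    }
    lib = {
        "ards": {
            **base,
            "fs_anat": ("uniform", 0.03, 0.10),
            "ncc_w1_per100": ("randint", 0, 10),
            "ncc_w2_per100": ("randint", 30, 60),
        },
        "cardiac": {
            **base,
            "sv": ("uniform", 35.0, 55.0),
            "fs_anat": ("uniform", 0.06, 0.11),
            "vo2": ("uniform", 160.0, 220.0),
            "hr": ("uniform", 90.0, 115.0),
            "delta_ncc_per100": ("randint", 0, 0),
            "sv_multiplier_w2": ("uniform", 0.45, 0.60),
        },
        "copd_like": {
            **base,
            "vd": ("uniform", 0.22, 0.30),
            "sigma_fr": ("uniform", 0.4, 0.8),
            "delta_ncc_per100": ("randint", 15, 28),
        },
        "control": {
            **base,
            "delta_ncc_per100": ("randint", 15, 28),
        },
    }
    return lib


def default_hospitals(n_total: int = 200) -> List[HospitalProfile]:
    """Three hospitals with distinct charting conventions and case mixes."""
    n_a = round(0.35 * n_total)
    n_b = round(0.325 * n_total)
    n_c = n_total - n_a - n_b
    return [
        HospitalProfile(
            "HospA", n_a, pao2_bias=5.0, peep_policy_offset=0.0,
            fio2_rounding=0.05, charting_interval=2.0, vt_per_kg_policy=6.0,
            archetype_mix={"ards": 0.25, "cardiac": 0.25,
                           "copd_like": 0.15, "control": 0.35}),
        HospitalProfile(
            "HospB", n_b, pao2_bias=0.0, peep_policy_offset=2.0,
            fio2_rounding=0.05, charting_interval=4.0, vt_per_kg_policy=7.0,
            archetype_mix={"ards": 0.20, "cardiac": 0.20,
                           "copd_like": 0.30, "control": 0.30}),
        HospitalProfile(
            "HospC", n_c, pao2_bias=-5.0, peep_policy_offset=-2.0,
            fio2_rounding=0.05, charting_interval=8.0, vt_per_kg_policy=8.0,
            archetype_mix={"ards": 0.30, "cardiac": 0.15,
                           "copd_like": 0.20, "control": 0.35}),
    ]


def _draw(rng: np.random.Generator, spec) -> float:
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "randint":
        return int(rng.integers(spec[1], spec[2] + 1))
    raise CohortConfigError(f"unknown distribution kind {kind!r}")


def _per100_to_count(per100: float, n_comp: int) -> int:
    return int(round(per100 * n_comp / 100.0))


def _generate_patient(
    rng: np.random.Generator,
    pid: str,
    profile: HospitalProfile,
    library: Mapping[str, dict],
    n_comp: int,
    noise: NoiseModel,
    p_dx: float,
) -> Tuple[PatientRecord, GroundTruthPatient]:
    archetypes = sorted(profile.archetype_mix)
    probs = np.array([profile.archetype_mix[a] for a in archetypes])
    archetype = str(rng.choice(archetypes, p=probs / probs.sum()))
    spec = library[archetype]

    params = {k: _draw(rng, spec[k]) for k in
              ("fs_anat", "rq", "vd", "vo2", "sv", "ie",
               "mu_fr", "sigma_fr", "mu_vr", "sigma_vr")}
    hr_base = _draw(rng, spec["hr"])
    ncc1_100 = _draw(rng, spec["ncc_w1_per100"])
    if "ncc_w2_per100" in spec:
        ncc2_100 = _draw(rng, spec["ncc_w2_per100"])
    else:
        ncc2_100 = ncc1_100 + _draw(rng, spec["delta_ncc_per100"])
    sv_mult = _draw(rng, spec["sv_multiplier_w2"])
    ncc1 = _per100_to_count(ncc1_100, n_comp)
    ncc2 = _per100_to_count(ncc2_100, n_comp)
    if archetype == "ards":
        ncc2 = max(ncc2, ncc1 + 1)
    ncc2 = min(ncc2, n_comp - 1)
    config_w1 = VPConfiguration(n_cc=ncc1, **params)

    # biometrics (independent coarse bins keep k-anonymity cells populated)
    age_bin = str(rng.choice(AGE_BINS))
    height_bin = str(rng.choice(HEIGHT_BINS))
    weight_bin = str(rng.choice(WEIGHT_BINS))
    bmi_bin = _BMI_MAP[(height_bin, weight_bin)]
    weight_kg = _WEIGHT_KG[weight_bin]
    vt = profile.vt_per_kg_policy * weight_kg

    mv_hours = (float(rng.uniform(48.0, 600.0)) if rng.random() < 0.95
                else float(rng.uniform(5.0, 23.0)))

    # suspected onset on the charting grid, so that the operational
    # P/F-based rule can recover it exactly (up to measurement noise)
    iv = profile.charting_interval
    candidates = np.arange(np.ceil(48.0 / iv), np.floor(120.0 / iv) + 1) * iv
    t0 = float(rng.choice(candidates))

    k_lo = int(np.ceil(max(0.0, t0 - 60.0) / iv))
    k_hi = int(np.floor((t0 + 36.0) / iv))
    times = np.arange(k_lo, k_hi + 1) * iv

    rr_base = float(rng.uniform(14.0, 20.0))
    fio2_w1 = float(rng.uniform(0.21, 0.26))
    fio2_w2 = float(np.clip(0.45 + 0.35 * (ncc2 * 100.0 / n_comp - 20.0) / 60.0,
                            0.45, 0.85))
    compliance_w1 = float(rng.uniform(40.0, 60.0))
    compliance_mult = (float(rng.uniform(0.45, 0.65)) if archetype == "ards"
                       else float(rng.uniform(0.75, 0.95)))
    # clinician discretion around the hospital PEEP policy: the policy
    # shifts the hospital's distribution without tagging every patient
    peep_jitter = float(rng.integers(-1, 2))

    # per 8h block: small deterministic-in-seed titrations of the settings
    blocks = np.unique((times // SETTINGS_BLOCK_HOURS).astype(int))
    block_rr = {b: float(np.clip(round(rr_base + rng.integers(-3, 4)), 10, 30))
                for b in blocks}
    block_hr = {b: float(hr_base + rng.uniform(-5.0, 5.0)) for b in blocks}
    block_dfio2 = {b: float(rng.uniform(-0.02, 0.02)) for b in blocks}
    # delivered tidal volume fluctuates around the policy setpoint
    # (pressure-regulated modes, spontaneous efforts)
    block_vt = {b: float(vt * rng.uniform(0.92, 1.08)) for b in blocks}

    diagnosed = archetype == "ards" and rng.random() < p_dx
    icd: List[str] = []
    if diagnosed:
        icd.append("J80")
    if archetype == "cardiac" and rng.random() < 0.85:
        icd.append("I50")
    if archetype == "copd_like" and rng.random() < 0.85:
        icd.append("J44")
    if rng.random() < 0.35:
        icd.append("I10")
    if rng.random() < 0.20:
        icd.append("E11")

    n_rows = times.size
    eps = {
        "pao2": rng.standard_normal(n_rows) * noise.pao2,
        "paco2": rng.standard_normal(n_rows) * noise.paco2,
        "ph": rng.standard_normal(n_rows) * noise.ph,
        "sao2": rng.standard_normal(n_rows) * noise.sao2,
        "pinsp": rng.standard_normal(n_rows) * noise.pinsp,
    }

    sim_cache: Dict[Tuple[bool, int], object] = {}
    rows: List[Tuple[float, str, float]] = []
    for j, t in enumerate(times):
        in_w2 = t >= t0
        b = int(t // SETTINGS_BLOCK_HOURS)
        fio2_true = float(np.clip(
            (fio2_w2 if in_w2 else fio2_w1) + block_dfio2[b], 0.21, 1.0))
        rr = block_rr[b]
        hr = block_hr[b]
        vt_b = block_vt[b]
        key = (in_w2, b)
        if key not in sim_cache:
            cfg = dataclasses.replace(
                config_w1,
                n_cc=ncc2 if in_w2 else ncc1,
                sv=params["sv"] * (sv_mult if in_w2 else 1.0))
            sim_cache[key] = simulate_steady_state(
                cfg, VentilatorInputs(fio2=fio2_true, vt=vt_b, rr=rr, hr=hr),
                n_comp=n_comp)
        sim = sim_cache[key]

        peep = (10.0 if archetype == "ards" else 8.0) if in_w2 else 5.0
        peep += profile.peep_policy_offset + peep_jitter
        compliance = compliance_w1 * (compliance_mult if in_w2 else 1.0)
        pinsp = peep + vt_b / compliance + eps["pinsp"][j]
        if profile.fio2_rounding > 0:
            fio2_chart = max(
                0.21, round(fio2_true / profile.fio2_rounding)
                * profile.fio2_rounding)
        else:
            fio2_chart = fio2_true
        t = float(t)
        rows.append((t, "pao2", sim.pao2 + profile.pao2_bias + eps["pao2"][j]))
        rows.append((t, "paco2", sim.paco2 + eps["paco2"][j]))
        rows.append((t, "ph", sim.ph + eps["ph"][j]))
        rows.append((t, "sao2",
                     float(np.clip(sim.sao2 + eps["sao2"][j], 0.2, 1.0))))
        rows.append((t, "fio2", fio2_chart))
        rows.append((t, "peep", peep))
        rows.append((t, "vt", vt_b))
        rows.append((t, "rr", rr))
        rows.append((t, "pinsp", pinsp))
        rows.append((t, "hr", hr))

    obs = pd.DataFrame(rows, columns=["time_h", "variable", "value"])
    record = PatientRecord(
        patient_id=pid, hospital_id=profile.hospital_id,
        age_bin=age_bin, height_bin=height_bin, weight_bin=weight_bin,
        bmi_bin=bmi_bin, icd_codes=icd, mv_hours=mv_hours, observations=obs)
    truth = GroundTruthPatient(
        patient_id=pid, hospital_id=profile.hospital_id, archetype=archetype,
        true_config_w1=config_w1, true_ncc_w2=ncc2, diagnosed_ards=diagnosed,
        t0=t0, sv_multiplier_w2=sv_mult)
    return record, truth


def generate_cohort(
    hospital_profiles: Sequence[HospitalProfile],
    archetype_library: Optional[Mapping[str, dict]] = None,
    seed: int = 0,
    n_comp: int = 20,
    noise: Optional[NoiseModel] = None,
    p_dx: float = 0.6,
) -> Tuple[List[PatientRecord], List[GroundTruthPatient]]:
    """Generate a reproducible multi-hospital cohort.

    The same (profiles, library, seed) always yields identical output;
    measurement effects and noise scaling never touch the random stream,
    so zero-effect / zero-noise reruns are pointwise comparable.
    """
    if len(hospital_profiles) < 2:
        raise CohortConfigError("at least 2 hospitals are required")
    library = dict(archetype_library or archetype_defaults())
    if not library:
        raise CohortConfigError("archetype library must not be empty")
    noise = noise if noise is not None else NoiseModel()
    ss = np.random.SeedSequence(seed)
    records: List[PatientRecord] = []
    truths: List[GroundTruthPatient] = []
    # one deterministic child stream per patient
    total = sum(p.n_patients for p in hospital_profiles)
    children = ss.spawn(total)
    idx = 0
    for profile in hospital_profiles:
        for j in range(profile.n_patients):
            pid = f"{profile.hospital_id}-{j + 1:04d}"
            rng = np.random.default_rng(children[idx])
            idx += 1
            rec, truth = _generate_patient(
                rng, pid, profile, library, n_comp, noise, p_dx)
            records.append(rec)
            truths.append(truth)
    return records, truths


# ---------------------------------------------------------------------------
# on-disk representation

def write_cohort(
    records: Sequence[PatientRecord],
    truths: Sequence[GroundTruthPatient],
    outdir,
    manifest_extra: Optional[dict] = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = pd.concat(
        [r.observations.assign(patient_id=r.patient_id) for r in records],
        ignore_index=True)[["patient_id", "time_h", "variable", "value"]]
    obs.to_csv(outdir / "observations.csv", index=False, float_format="%.6f")
    pats = pd.DataFrame(
        [{
            "patient_id": r.patient_id, "hospital_id": r.hospital_id,
            "age_bin": r.age_bin, "height_bin": r.height_bin,
            "weight_bin": r.weight_bin, "bmi_bin": r.bmi_bin,
            "icd_codes": ";".join(r.icd_codes), "mv_hours": r.mv_hours,
        } for r in records])
    pats.to_csv(outdir / "patients.csv", index=False, float_format="%.6f")
    gt_rows = []
    for t in truths:
        row = {
            "patient_id": t.patient_id, "hospital_id": t.hospital_id,
            "archetype": t.archetype, "t0": t.t0,
            "diagnosed_ards": t.diagnosed_ards,
            "true_ncc_w2": t.true_ncc_w2,
            "sv_multiplier_w2": t.sv_multiplier_w2,
        }
        for name, val in zip(VPConfiguration.param_names(),
                             t.true_config_w1.as_vector()):
            row[f"true_{name}"] = val
        gt_rows.append(row)
    pd.DataFrame(gt_rows).to_csv(
        outdir / "ground_truth.csv", index=False, float_format="%.6f")
    manifest = dict(manifest_extra or {})
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_cohort(indir) -> Tuple[List[PatientRecord], List[GroundTruthPatient]]:
    indir = Path(indir)
    obs = pd.read_csv(indir / "observations.csv")
    pats = pd.read_csv(indir / "patients.csv")
    records = []
    for _, row in pats.iterrows():
        codes = (str(row["icd_codes"]).split(";")
                 if isinstance(row["icd_codes"], str) and row["icd_codes"]
                 else [])
        po = obs[obs["patient_id"] == row["patient_id"]]
        records.append(PatientRecord(
            patient_id=row["patient_id"], hospital_id=row["hospital_id"],
            age_bin=row["age_bin"], height_bin=row["height_bin"],
            weight_bin=row["weight_bin"], bmi_bin=row["bmi_bin"],
            icd_codes=codes, mv_hours=float(row["mv_hours"]),
            observations=po[["time_h", "variable", "value"]].reset_index(
                drop=True)))
    truths: List[GroundTruthPatient] = []
    gt_path = indir / "ground_truth.csv"
    if gt_path.exists():
        gt = pd.read_csv(gt_path)
        for _, row in gt.iterrows():
            cfg = VPConfiguration.from_vector(np.array(
                [row[f"true_{n}"] for n in VPConfiguration.param_names()]))
            truths.append(GroundTruthPatient(
                patient_id=row["patient_id"], hospital_id=row["hospital_id"],
                archetype=row["archetype"], true_config_w1=cfg,
                true_ncc_w2=int(row["true_ncc_w2"]),
                diagnosed_ards=bool(row["diagnosed_ards"]), t0=float(row["t0"]),
                sv_multiplier_w2=float(row["sv_multiplier_w2"])))
    return records, truths
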