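"""Matching the gas-exchange model to individual patients.

Window 1 (pre-onset steady state): all 11 virtual-patient parameters are
fitted to the charted arterial blood gases by surrogate-based global
minimization.  Window 2 (post-onset): only the number of closed
compartments is re-fitted, with the window-1 configuration held fixed,
so disease progression is expressed through a single interpretable
parameter.  Fit quality is classified per window (simulated gas means
within 2 SD of the charted values) and acceptable fits are summarized
into 18 model-derived features per patient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gas_exchange import (
    DomainError,
    VPConfiguration,
    VentilatorInputs,
    simulate_steady_state,
)
from .preprocessing import EligiblePatient
from .rbfopt import minimize_rbf

__all__ = [
    "GASES",
    "OBJECTIVE_SCALES",
    "DEFAULT_BOUNDS",
    "FitResult",
    "ModelDerivedFeatures",
    "objective",
    "simulate_window",
    "fit_window1",
    "fit_window2",
    "assess_fit",
    "model_derived_features",
    "fit_patient",
]

GASES = ("pao2", "paco2", "sao2", "ph")
# natural disagreement scales used to make the 4 gas residuals commensurate
OBJECTIVE_SCALES = {"pao2": 10.0, "paco2": 4.0, "sao2": 0.02, "ph": 0.04}
NONCONVERGENCE_PENALTY = 1e3

# physiological search box for the 11 window-1 parameters; n_cc bounds are
# per 100 compartments and are scaled to the working compartment count
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "fs_anat": (0.01, 0.35),
    "rq": (0.7, 1.0),
    "vd": (0.10, 0.30),
    "vo2": (150.0, 400.0),
    "sv": (40.0, 120.0),
    "ie": (0.25, 1.0),
    "mu_fr": (-1.0, 1.0),
    "sigma_fr": (0.0, 0.8),
    "mu_vr": (-1.0, 1.0),
    "sigma_vr": (0.0, 0.8),
    "n_cc_per100": (0.0, 95.0),
}

MODEL_FEATURE_NAMES = (
    "fs_anat", "rq", "vd", "vo2", "sv", "ie", "mu_fr", "sigma_fr",
    "mu_vr", "sigma_vr", "ncc_w1", "ncc_w2", "delta_ncc",
    "va_total@w1", "va_total@w2",
    "shunt_fraction@w1", "shunt_fraction@w2", "svo2@w2",
)


@dataclass
class FitResult:
    patient_id: str
    config_w1: VPConfiguration
    ncc_w2: int
    obj_w1: float
    obj_w2: float
    acceptable_w1: bool
    acceptable_w2: bool
    n_sim_calls: int


@dataclass(frozen=True)
class ModelDerivedFeatures:
    patient_id: str
    values: Dict[str, float]


class _SimCounter:
    def __init__(self) -> None:
        self.n = 0


def _window_input_groups(window: pd.DataFrame):
    """Group charted rows by their (rounded) ventilator-input tuple."""
    cols = ["fio2", "vt", "rr", "hr"]
    key = window[cols].round(6)
    return window.groupby([key[c] for c in cols], sort=False)


def simulate_window(
    config: VPConfiguration,
    window: pd.DataFrame,
    n_comp: int = 20,
    counter: Optional[_SimCounter] = None,
) -> pd.DataFrame:
    """Simulate every charted timestamp of a window with its own inputs.

    Identical input tuples share one steady-state solution.  Failed or
    non-converged solutions are flagged rather than raised, so callers
    can penalize them.
    """
    out = pd.DataFrame(
        index=window.index,
        columns=["pao2", "paco2", "sao2", "ph", "va_total",
                 "shunt_fraction", "svo2", "failed"], dtype=float)
    for (fio2, vt, rr, hr), grp in _window_input_groups(window):
        if counter is not None:
            counter.n += 1
        try:
            sim = simulate_steady_state(
                config,
                VentilatorInputs(fio2=float(fio2), vt=float(vt),
                                 rr=float(rr), hr=float(hr)),
                n_comp=n_comp)
            vals = (sim.pao2, sim.paco2, sim.sao2, sim.ph, sim.va_total,
                    sim.shunt_fraction_total, sim.svo2,
                    0.0 if sim.converged else 1.0)
        except DomainError:
            vals = (np.nan,) * 7 + (1.0,)
        out.loc[grp.index, :] = vals
    return out


def objective(
    config: VPConfiguration,
    window: pd.DataFrame,
    n_comp: int = 20,
    counter: Optional[_SimCounter] = None,
) -> float:
    """Mean over timestamps of the squared scaled gas residuals.

    Per timestamp the simulator runs with that timestamp's charted
    ventilator inputs; residuals for PaO2, PaCO2, SaO2 and pH are scaled
    by (10 mmHg, 4 mmHg, 0.02, 0.04).  Any non-converged or failed
    timestamp adds a fixed penalty of 1e3.
    """
    if window.empty:
        raise ValueError("window has no charted rows")
    sims = simulate_window(config, window, n_comp=n_comp, counter=counter)
    score = np.zeros(len(window))
    for gas in GASES:
        resid = (sims[gas].to_numpy() - window[gas].to_numpy()) \
            / OBJECTIVE_SCALES[gas]
        score += np.where(np.isnan(resid), 0.0, resid ** 2)
    obj = float(np.mean(score))
    if sims["failed"].to_numpy().any():
        obj += NONCONVERGENCE_PENALTY
    return obj


def _bounds_array(bounds: Mapping[str, Tuple[float, float]],
                  n_comp: int) -> np.ndarray:
    b = [bounds[k] for k in ("fs_anat", "rq", "vd", "vo2", "sv", "ie",
                             "mu_fr", "sigma_fr", "mu_vr", "sigma_vr")]
    lo100, hi100 = bounds["n_cc_per100"]
    ncc_hi = min(hi100 * n_comp / 100.0, n_comp - 1)
    b.append((lo100 * n_comp / 100.0, ncc_hi))
    return np.asarray(b, dtype=float)


def fit_window1(
    window: pd.DataFrame,
    seed: int = 0,
    budget: int = 100,
    n_comp: int = 20,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    counter: Optional[_SimCounter] = None,
) -> Tuple[VPConfiguration, float]:
    """Global fit of the 11-parameter configuration to window-1 gases.

    n_cc is relaxed to a continuous coordinate during the search and
    rounded on every evaluation.  Deterministic under a fixed seed.
    """
    if budget < 11:
        raise ValueError("optimizer budget must be at least 11")
    barr = _bounds_array(bounds or DEFAULT_BOUNDS, n_comp)

    def f(x: np.ndarray) -> float:
        return objective(VPConfiguration.from_vector(x), window,
                         n_comp=n_comp, counter=counter)

    res = minimize_rbf(f, barr, budget=budget, seed=seed)
    return VPConfiguration.from_vector(res.x), float(res.fun)


def fit_window2(
    window: pd.DataFrame,
    config_w1: VPConfiguration,
    n_comp: int = 20,
    counter: Optional[_SimCounter] = None,
) -> Tuple[int, float]:
    """Re-fit only the number of closed compartments on window-2 data.

    Exhaustive scan over the integer grid when it has at most 100 points,
    golden-section search on the rounded relaxation otherwise.
    """
    grid = list(range(config_w1.n_cc, n_comp))
    def f(ncc: int) -> float:
        return objective(dataclasses.replace(config_w1, n_cc=int(ncc)),
                         window, n_comp=n_comp, counter=counter)
    if len(grid) <= 100:
        objs = [f(ncc) for ncc in grid]
        i = int(np.argmin(objs))
        return grid[i], float(objs[i])
    # golden-section on the continuous relaxation, rounding on evaluation
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = float(grid[0]), float(grid[-1])
    cache: Dict[int, float] = {}
    def fr(x: float) -> float:
        k = int(round(x))
        if k not in cache:
            cache[k] = f(k)
        return cache[k]
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = fr(c), fr(d)
    while b - a > 1.0:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fr(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fr(d)
    k_best = min(cache, key=cache.get)
    return k_best, cache[k_best]


def assess_fit(sims: pd.DataFrame, window: pd.DataFrame) -> bool:
    """Acceptable fit: simulated gas means within 2 SD of charted means.

    Per gas the SD is the sample SD of that gas's charted values in the
    window; with fewer than 3 rows the objective scales serve as
    fallback spread estimates.
    """
    for gas in GASES:
        obs = window[gas].dropna()
        sd = float(obs.std(ddof=1)) if len(obs) >= 3 else OBJECTIVE_SCALES[gas]
        sim_mean = float(sims[gas].mean())
        if np.isnan(sim_mean):
            return False
        if abs(sim_mean - float(obs.mean())) > 2.0 * sd:
            return False
    return True


def fit_patient(
    patient: EligiblePatient,
    seed: int = 0,
    budget: int = 100,
    n_comp: int = 20,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FitResult:
    """Two-window matching for one eligible patient."""
    counter = _SimCounter()
    w1, w2 = patient.slices["w1"], patient.slices["w2"]
    config_w1, obj_w1 = fit_window1(
        w1, seed=seed, budget=budget, n_comp=n_comp, bounds=bounds,
        counter=counter)
    ncc_w2, obj_w2 = fit_window2(w2, config_w1, n_comp=n_comp, counter=counter)
    sims_w1 = simulate_window(config_w1, w1, n_comp=n_comp)
    sims_w2 = simulate_window(
        dataclasses.replace(config_w1, n_cc=ncc_w2), w2, n_comp=n_comp)
    return FitResult(
        patient_id=patient.record.patient_id,
        config_w1=config_w1, ncc_w2=ncc_w2,
        obj_w1=float(obj_w1), obj_w2=float(obj_w2),
        acceptable_w1=assess_fit(sims_w1, w1),
        acceptable_w2=assess_fit(sims_w2, w2),
        n_sim_calls=counter.n)


def model_derived_features(
    fit: FitResult,
    slices: Mapping[str, pd.DataFrame],
    n_comp: int = 20,
) -> ModelDerivedFeatures:
    """The 18 model-derived features of an acceptably fitted patient.

    Comprises the 11 fitted window-1 parameters, the window-2 closed
    compartment count and its increase, and simulator summary outputs
    (total alveolar ventilation per window, total shunt fraction per
    window, mixed-venous O2 saturation after onset).
    """
    if not (fit.acceptable_w1 and fit.acceptable_w2):
        raise ValueError(
            f"patient {fit.patient_id}: model-derived features require an "
            "acceptable fit in both windows")
    sims_w1 = simulate_window(fit.config_w1, slices["w1"], n_comp=n_comp)
    sims_w2 = simulate_window(
        dataclasses.replace(fit.config_w1, n_cc=fit.ncc_w2),
        slices["w2"], n_comp=n_comp)
    cfg = fit.config_w1
    values = {
        "fs_anat": cfg.fs_anat, "rq": cfg.rq, "vd": cfg.vd, "vo2": cfg.vo2,
        "sv": cfg.sv, "ie": cfg.ie, "mu_fr": cfg.mu_fr,
        "sigma_fr": cfg.sigma_fr, "mu_vr": cfg.mu_vr,
        "sigma_vr": cfg.sigma_vr,
        "ncc_w1": float(cfg.n_cc), "ncc_w2": float(fit.ncc_w2),
        "delta_ncc": float(fit.ncc_w2 - cfg.n_cc),
        "va_total@w1": float(sims_w1["va_total"].mean()),
        "va_total@w2": float(sims_w2["va_total"].mean()),
        "shunt_fraction@w1": float(sims_w1["shunt_fraction"].mean()),
        "shunt_fraction@w2": float(sims_w2["shunt_fraction"].mean()),
        "svo2@w2": float(sims_w2["svo2"].mean()),
    }
    assert len(values) == 18
    return ModelDerivedFeatures(patient_id=fit.patient_id, values=values)
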