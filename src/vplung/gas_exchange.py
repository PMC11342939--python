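"""Steady-state multi-compartment lung gas exchange.

The lung is a set of alveolar compartments with heterogeneous flow
(airway) and vascular resistances, so ventilation/perfusion mismatch,
anatomical shunt, dead space and atelectasis can all be represented.
ARDS-like deterioration is modelled by *closing* compartments: a closed
compartment receives perfusion but no ventilation, i.e. it behaves as a
complete alveolar shunt.

Per-compartment steady-state gas balances (O2 via the Severinghaus
dissociation curve, CO2 via a linearized content relation) are combined
with flow-weighted venous admixture and a Fick update of mixed-venous
contents, iterated to a fixed point.  The cardiovascular pressure-volume
system and airway mechanics are out of scope; PEEP and pressures are
carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from numba import njit
from scipy.special import ndtri

__all__ = [
    "VPConfiguration",
    "VentilatorInputs",
    "CompartmentState",
    "SimulationResult",
    "DomainError",
    "ZeroAlveolarVentilationError",
    "AllCompartmentsClosedError",
    "UnsustainableVO2Error",
    "o2_saturation",
    "o2_content",
    "co2_content",
    "compartment_resistances",
    "distribute_flows",
    "simulate_steady_state",
]

# blood-gas constants
HUFNER = 1.34          # mL O2 bound per g hemoglobin at full saturation
O2_SOLUBILITY = 0.003  # mL O2 / dL blood / mmHg, dissolved
CO2_SLOPE = 0.45       # mL CO2 / dL blood / mmHg (linearized content curve)
CO2_INTERCEPT = 26.7   # mL CO2 / dL blood at PCO2 = 0 on the linearization
BICARBONATE = 24.0     # mmol/L, fixed for the Henderson-Hasselbalch pH
PV_O2_INIT = 40.0      # mmHg, initial mixed-venous PO2 guess
PV_CO2_INIT = 46.0     # mmHg, initial mixed-venous PCO2 guess


class DomainError(ValueError):
    """An argument is outside its physical/physiological domain."""


class ZeroAlveolarVentilationError(DomainError):
    """Tidal volume does not exceed dead space: no alveolar ventilation."""


class AllCompartmentsClosedError(DomainError):
    """n_cc must leave at least one compartment open."""


class UnsustainableVO2Error(DomainError):
    """Metabolic O2 demand exceeds what the circulation can deliver."""


@dataclass(frozen=True)
class VPConfiguration:
    """The individualized ('virtual patient') model parameterization.

    These are the 11 quantities determined per patient in the window-1
    matching step.  Resistances are described by log-normal location and
    scale; per-compartment values are deterministic quantiles, not draws.
    """

    fs_anat: float   # anatomical shunt fraction (0-1)
    rq: float        # respiratory quotient (VCO2/VO2)
    vd: float        # anatomical dead space volume, L
    vo2: float       # metabolic O2 consumption, mL/min STPD
    sv: float        # cardiac stroke volume, mL
    ie: float        # inspiration:expiration ratio (metadata, fitted)
    mu_fr: float     # log-normal location of compartment flow resistance
    sigma_fr: float  # log-normal scale of compartment flow resistance
    mu_vr: float     # log-normal location of compartment vascular resistance
    sigma_vr: float  # log-normal scale of compartment vascular resistance
    n_cc: int        # number of closed alveolar compartments

    def __post_init__(self) -> None:
        if not 0.0 <= self.fs_anat <= 1.0:
            raise DomainError(f"fs_anat={self.fs_anat} outside [0, 1]")
        if not 0.6 <= self.rq <= 1.1:
            raise DomainError(f"rq={self.rq} outside [0.6, 1.1]")
        if self.vd <= 0:
            raise DomainError("vd must be positive")
        if self.vo2 < 0:
            raise DomainError("vo2 must be non-negative")
        if self.sv <= 0:
            raise DomainError("sv must be positive")
        if self.ie <= 0:
            raise DomainError("ie must be positive")
        if self.sigma_fr < 0 or self.sigma_vr < 0:
            raise DomainError("resistance sigmas must be non-negative")
        if int(self.n_cc) != self.n_cc or self.n_cc < 0:
            raise DomainError("n_cc must be a non-negative integer")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.fs_anat, self.rq, self.vd, self.vo2, self.sv, self.ie,
             self.mu_fr, self.sigma_fr, self.mu_vr, self.sigma_vr,
             float(self.n_cc)]
        )

    @staticmethod
    def param_names() -> Tuple[str, ...]:
        return ("fs_anat", "rq", "vd", "vo2", "sv", "ie", "mu_fr",
                "sigma_fr", "mu_vr", "sigma_vr", "n_cc")

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "VPConfiguration":
        x = np.asarray(x, dtype=float)
        return cls(*x[:10], n_cc=int(round(x[10])))


@dataclass(frozen=True)
class VentilatorInputs:
    """Charted ventilator settings and ambient/blood constants."""

    fio2: float          # inspired O2 fraction
    vt: float            # tidal volume, mL
    rr: float            # respiratory rate, /min
    peep: float = 5.0    # cmH2O (metadata only)
    hr: float = 80.0     # heart rate, /min
    hb: float = 12.0     # hemoglobin, g/dL
    pb: float = 760.0    # barometric pressure, mmHg
    ph2o: float = 47.0   # water vapor pressure, mmHg
    temp: float = 37.0   # body temperature, degC (metadata only)

    def __post_init__(self) -> None:
        if not 0.21 <= self.fio2 <= 1.0:
            raise DomainError(f"fio2={self.fio2} outside [0.21, 1.0]")
        if self.vt <= 0 or self.rr <= 0 or self.hr <= 0 or self.hb < 0:
            raise DomainError("vt, rr, hr must be positive; hb non-negative")
        if self.pb <= self.ph2o:
            raise DomainError("barometric pressure must exceed ph2o")


@dataclass(frozen=True)
class CompartmentState:
    v_dot: float    # alveolar ventilation, L/min
    q_dot: float    # perfusion, L/min
    pa_o2: float    # alveolar PO2, mmHg
    pa_co2: float   # alveolar PCO2, mmHg
    cc_o2: float    # end-capillary O2 content, mL/dL
    cc_co2: float   # end-capillary CO2 content, mL/dL
    closed: bool


@dataclass(frozen=True)
class SimulationResult:
    pao2: float
    paco2: float
    sao2: float
    ph: float
    svo2: float
    va_total: float
    q_total: float
    shunt_fraction_total: float
    converged: bool
    n_iter: int
    cao2: float
    cvo2: float
    cvco2: float
    o2_uptake: float    # ventilation-side O2 uptake, mL/min
    _v_dot: np.ndarray = field(repr=False)
    _q_dot: np.ndarray = field(repr=False)
    _pa_o2: np.ndarray = field(repr=False)
    _pa_co2: np.ndarray = field(repr=False)
    _cc_o2: np.ndarray = field(repr=False)
    _cc_co2: np.ndarray = field(repr=False)
    _closed: np.ndarray = field(repr=False)

    @property
    def compartments(self) -> Tuple[CompartmentState, ...]:
        return tuple(
            CompartmentState(
                float(self._v_dot[i]), float(self._q_dot[i]),
                float(self._pa_o2[i]), float(self._pa_co2[i]),
                float(self._cc_o2[i]), float(self._cc_co2[i]),
                bool(self._closed[i]),
            )
            for i in range(self._v_dot.shape[0])
        )


def o2_saturation(po2):
    """Hemoglobin O2 saturation (Severinghaus form), fraction in (0, 1).

    S = 1 / (1 + 23400 / (PO2^3 + 150 PO2)); strictly increasing in PO2.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 <= 0):
        raise DomainError("po2 must be positive")
    s = 1.0 / (1.0 + 23400.0 / (po2 ** 3 + 150.0 * po2))
    return float(s) if s.ndim == 0 else s


def o2_content(po2, hb):
    """Blood O2 content, mL O2/dL = 1.34*hb*S(po2) + 0.003*po2."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 <= 0):
        raise DomainError("po2 must be positive")
    if np.any(np.asarray(hb) < 0):
        raise DomainError("hb must be non-negative")
    c = HUFNER * hb * o2_saturation(po2) + O2_SOLUBILITY * po2
    return float(c) if np.ndim(c) == 0 else c


def co2_content(pco2):
    """Blood CO2 content, mL/dL; linearized around the physiological range."""
    pco2 = np.asarray(pco2, dtype=float)
    if np.any(pco2 < 0):
        raise DomainError("pco2 must be non-negative")
    c = CO2_SLOPE * pco2 + CO2_INTERCEPT
    return float(c) if c.ndim == 0 else c


def blood_ph(paco2: float) -> float:
    """Henderson-Hasselbalch pH with fixed bicarbonate (24 mmol/L)."""
    if paco2 <= 0:
        raise DomainError("paco2 must be positive")
    return 6.1 + np.log10(BICARBONATE / (0.03 * paco2))


def compartment_resistances(mu: float, sigma: float, n_comp: int) -> np.ndarray:
    """Deterministic log-normal quantile resistances for n_comp compartments.

    r_i = exp(mu + sigma * Phi^-1((i - 0.5)/n_comp)), i = 1..n_comp.
    Quantiles (not random draws) keep the simulator bit-reproducible: the
    distribution parameters, not individual draws, are the fitted objects.
    """
    if n_comp < 1:
        raise DomainError("n_comp must be >= 1")
    q = (np.arange(1, n_comp + 1) - 0.5) / n_comp
    return np.exp(mu + sigma * ndtri(q))


def _decorrelating_permutation(n: int) -> np.ndarray:
    """Deterministic low-discrepancy ordering (van der Corput, base 2)."""
    vdc = np.empty(n)
    for i in range(n):
        x, denom, v = i, 1.0, 0.0
        while x:
            denom *= 2.0
            x, rem = divmod(x, 2)
            v += rem / denom
        vdc[i] = v
    return np.argsort(vdc, kind="stable")


def closed_mask(config: VPConfiguration, n_comp: int) -> np.ndarray:
    """Closed compartments are the n_cc of highest flow resistance."""
    if config.n_cc >= n_comp:
        raise AllCompartmentsClosedError(
            f"n_cc={config.n_cc} must be < n_comp={n_comp}")
    mask = np.zeros(n_comp, dtype=bool)
    if config.n_cc > 0:
        # resistances are increasing in the quantile index
        mask[n_comp - config.n_cc:] = True
    return mask


def distribute_flows(
    config: VPConfiguration, inputs: VentilatorInputs, n_comp: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Split total alveolar ventilation and non-shunted perfusion.

    Ventilation VA = (vt/1000 - vd) * rr goes to open compartments in
    proportion to 1/flow-resistance; perfusion Q*(1 - fs_anat) with
    Q = sv*hr/1000 goes to all compartments (closed ones included) in
    proportion to 1/vascular-resistance.
    """
    if n_comp < 1:
        raise DomainError("n_comp must be >= 1")
    closed = closed_mask(config, n_comp)
    va = (inputs.vt / 1000.0 - config.vd) * inputs.rr
    if va <= 0:
        raise ZeroAlveolarVentilationError(
            f"tidal volume {inputs.vt} mL does not exceed dead space "
            f"{config.vd} L: zero alveolar ventilation")
    r_fr = compartment_resistances(config.mu_fr, config.sigma_fr, n_comp)
    # The two resistance distributions are marginals; their joint coupling
    # is not a fitted quantity.  A deterministic low-discrepancy (bit
    # reversal) pairing decorrelates them, so ventilation and perfusion
    # heterogeneity act as independent axes of V/Q mismatch and closed
    # compartments carry an approximately proportional perfusion share.
    r_vr = compartment_resistances(config.mu_vr, config.sigma_vr, n_comp)[
        _decorrelating_permutation(n_comp)]
    g_fr = np.where(closed, 0.0, 1.0 / r_fr)
    v_dot = va * g_fr / g_fr.sum()
    q_total = config.sv * inputs.hr / 1000.0
    g_vr = 1.0 / r_vr
    q_dot = q_total * (1.0 - config.fs_anat) * g_vr / g_vr.sum()
    return v_dot, q_dot


@njit(cache=True)
def _sat(p):
    return 1.0 / (1.0 + 23400.0 / (p * p * p + 150.0 * p))


@njit(cache=True)
def _o2c(p, hb):
    return 1.34 * hb * _sat(p) + 0.003 * p


@njit(cache=True)
def _invert_o2_content(c, hb):
    """PO2 such that o2_content(PO2, hb) = c; bisection on [1e-3, 900]."""
    lo, hi = 1e-3, 900.0
    if c <= _o2c(lo, hb):
        return lo
    if c >= _o2c(hi, hb):
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _o2c(mid, hb) < c:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def _solve_po2(kv, q, p_insp, cv, hb):
    """Alveolar PO2 from the compartment O2 balance (monotone bisection).

    kv*(P_I - p) = 10*q*(C(p) - cv); LHS decreasing, RHS increasing in p.
    """
    if q <= 0.0:
        return p_insp  # no perfusion: alveolar gas equilibrates to inspired
    lo = 0.5
    hi = p_insp
    flo = kv * (p_insp - lo) - 10.0 * q * (_o2c(lo, hb) - cv)
    if flo <= 0.0:
        return lo
    fhi = -10.0 * q * (_o2c(hi, hb) - cv)
    if fhi >= 0.0:
        return hi
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        fm = kv * (p_insp - mid) - 10.0 * q * (_o2c(mid, hb) - cv)
        if fm > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def _steady_core(v_dot, q_dot, closed, fio2, pb, ph2o, hb, q_total,
                 fs_anat, vo2, rq, tol, max_iter, cv_o2_0, cv_co2_0):
    n = v_dot.shape[0]
    p_insp = fio2 * (pb - ph2o)
    pfac = pb - ph2o

    q_shunt = fs_anat * q_total
    for i in range(n):
        if closed[i]:
            q_shunt += q_dot[i]
    s = q_shunt / q_total

    # --- CO2: the linear content relation admits an exact solution ---
    b = rq * vo2 / (10.0 * q_total)
    a_arr = np.zeros(n)
    A = 0.0
    for i in range(n):
        if not closed[i]:
            kv = 1000.0 * v_dot[i] / pfac
            den = kv + 4.5 * q_dot[i]
            if den > 0.0:
                a_arr[i] = 10.0 * q_dot[i] / den
            A += 0.45 * q_dot[i] * a_arr[i] / q_total
    denom = 1.0 - A - s
    status = 0
    if denom < 1e-9:
        if b > 1e-12:
            # no effective CO2 elimination but nonzero production
            status = 2
        cv_co2 = cv_co2_0
    else:
        cv_co2 = 26.7 + b / denom
    ca_co2 = cv_co2 - b
    paco2 = (ca_co2 - 26.7) / 0.45
    if paco2 < 0.5:
        paco2 = 0.5
    pa_co2 = np.empty(n)
    cc_co2 = np.empty(n)
    pv_co2 = (cv_co2 - 26.7) / 0.45
    if pv_co2 < 0.5:
        pv_co2 = 0.5
    for i in range(n):
        if closed[i]:
            pa_co2[i] = pv_co2
            cc_co2[i] = cv_co2
        else:
            p = a_arr[i] * (cv_co2 - 26.7)
            if p < 0.0:
                p = 0.0
            pa_co2[i] = p
            cc_co2[i] = 0.45 * p + 26.7

    # --- O2: fixed point on mixed-venous content ---
    cv = cv_o2_0
    pa_o2 = np.empty(n)
    cc_o2 = np.empty(n)
    converged = False
    n_iter = 0
    ca = cv
    if status == 0:
        for it in range(max_iter):
            n_iter = it + 1
            ca_num = q_shunt * cv
            for i in range(n):
                if closed[i]:
                    pa_o2[i] = 0.0
                    cc_o2[i] = cv
                else:
                    kv = 1000.0 * v_dot[i] / pfac
                    p = _solve_po2(kv, q_dot[i], p_insp, cv, hb)
                    pa_o2[i] = p
                    c = _o2c(p, hb)
                    cc_o2[i] = c
                    ca_num += q_dot[i] * c
            ca = ca_num / q_total
            cv_new = ca - vo2 / (10.0 * q_total)
            if cv_new < 0.05:
                status = 1  # unsustainable O2 demand
                break
            rel = abs(cv_new - cv) / max(cv, 1e-9)
            cv = cv_new
            if rel < tol:
                converged = True
                break
    # ventilation-side O2 uptake for the mass-balance audit
    uptake = 0.0
    for i in range(n):
        if not closed[i]:
            kv = 1000.0 * v_dot[i] / pfac
            uptake += kv * (p_insp - pa_o2[i])
    pv_o2 = _invert_o2_content(cv, hb) if hb > 0 else cv / 0.003
    pao2 = _invert_o2_content(ca, hb) if hb > 0 else ca / 0.003
    # closed compartments see mixed-venous gas
    for i in range(n):
        if closed[i]:
            pa_o2[i] = pv_o2
    return (status, converged, n_iter, pao2, paco2, ca, cv, cv_co2,
            uptake, pa_o2, pa_co2, cc_o2, cc_co2, pv_o2)


def simulate_steady_state(
    config: VPConfiguration,
    inputs: VentilatorInputs,
    n_comp: int = 100,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> SimulationResult:
    """Run the multi-compartment gas-exchange model to steady state.

    Fixed-point loop on mixed-venous blood contents: per open compartment
    solve the alveolar O2 balance (CO2 has a closed-form solution under
    the linear content relation), mix end-capillary blood flow-weighted
    with shunted venous blood (anatomical + closed compartments), and
    update venous contents by the Fick principle.  Non-convergence within
    ``max_iter`` is reported via ``converged=False`` (no exception);
    impossible O2 demand raises :class:`UnsustainableVO2Error`.
    """
    v_dot, q_dot = distribute_flows(config, inputs, n_comp)
    closed = closed_mask(config, n_comp)
    q_total = config.sv * inputs.hr / 1000.0
    cv_o2_0 = o2_content(PV_O2_INIT, inputs.hb)
    cv_co2_0 = co2_content(PV_CO2_INIT)
    (status, converged, n_iter, pao2, paco2, ca, cv, cv_co2, uptake,
     pa_o2, pa_co2, cc_o2, cc_co2, pv_o2) = _steady_core(
        v_dot, q_dot, closed, inputs.fio2, inputs.pb, inputs.ph2o,
        inputs.hb, q_total, config.fs_anat, config.vo2, config.rq,
        tol, max_iter, cv_o2_0, cv_co2_0)
    if status != 0:
        raise UnsustainableVO2Error(
            "metabolic O2 demand cannot be met by the modelled circulation")
    if converged and config.vo2 > 0:
        converged = abs(uptake - config.vo2) / config.vo2 <= 0.01
    q_shunt = config.fs_anat * q_total + float(q_dot[closed].sum())
    return SimulationResult(
        pao2=float(pao2),
        paco2=float(paco2),
        sao2=float(o2_saturation(pao2)),
        ph=float(blood_ph(paco2)),
        svo2=float(o2_saturation(pv_o2)),
        va_total=float(v_dot.sum()),
        q_total=float(q_total),
        shunt_fraction_total=float(q_shunt / q_total),
        converged=bool(converged),
        n_iter=int(n_iter),
        cao2=float(ca),
        cvo2=float(cv),
        cvco2=float(cv_co2),
        o2_uptake=float(uptake),
        _v_dot=v_dot,
        _q_dot=q_dot,
        _pa_o2=pa_o2,
        _pa_co2=pa_co2,
        _cc_o2=cc_o2,
        _cc_co2=cc_co2,
        _closed=closed,
    )
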