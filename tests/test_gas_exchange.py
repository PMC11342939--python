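import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vplung.gas_exchange import (
    AllCompartmentsClosedError,
    DomainError,
    UnsustainableVO2Error,
    VPConfiguration,
    VentilatorInputs,
    ZeroAlveolarVentilationError,
    compartment_resistances,
    distribute_flows,
    o2_content,
    o2_saturation,
    simulate_steady_state,
)


def config(**kw) -> VPConfiguration:
    base = dict(fs_anat=0.05, rq=0.8, vd=0.15, vo2=250.0, sv=80.0, ie=0.5,
                mu_fr=0.0, sigma_fr=0.3, mu_vr=0.0, sigma_vr=0.3, n_cc=0)
    base.update(kw)
    return VPConfiguration(**base)


def homogeneous(**kw) -> VPConfiguration:
    return config(sigma_fr=0.0, sigma_vr=0.0, fs_anat=0.0, n_cc=0, **kw)


class TestDissociationCurve:
    @pytest.mark.parametrize("po2, expected, tol", [
        (26.8, 0.499, 1e-3),   # near the P50 of adult hemoglobin
        (100.0, 0.977, 1e-3),
    ])
    def test_known_points(self, po2, expected, tol):
        assert o2_saturation(po2) == pytest.approx(expected, abs=tol)

    def test_asymptote(self):
        assert o2_saturation(600.0) > 0.999
        assert o2_saturation(600.0) < 1.0

    @given(st.floats(min_value=1.0, max_value=600.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, po2):
        s = o2_saturation(po2)
        assert 0.0 < s < 1.0
        assert o2_saturation(po2 + 1.0) > s

    def test_domain_error(self):
        with pytest.raises(DomainError):
            o2_saturation(0.0)
        with pytest.raises(DomainError):
            o2_content(-5.0, 15.0)


class TestO2Content:
    def test_dissolved_only(self):
        assert o2_content(100.0, 0.0) == pytest.approx(0.3)

    def test_normal_blood(self):
        assert o2_content(100.0, 15.0) == pytest.approx(19.95, abs=0.01)

    def test_monotone_in_both_arguments(self):
        assert o2_content(60.0, 15.0) < o2_content(100.0, 15.0)
        assert o2_content(100.0, 12.0) < o2_content(100.0, 15.0)


class TestFlowDistribution:
    def test_homogeneous_equal_split(self):
        cfg = homogeneous()
        inp = VentilatorInputs(fio2=0.3, vt=500.0, rr=15.0, hr=75.0)
        v, q = distribute_flows(cfg, inp, n_comp=10)
        va = (0.5 - cfg.vd) * 15.0
        qt = cfg.sv * 75.0 / 1000.0
        assert np.allclose(v, va / 10)
        assert np.allclose(q, qt / 10)

    def test_alveolar_ventilation_value(self):
        # VA = (vt/1000 - vd) * rr = (0.5 - 0.15) * 15 = 5.25 L/min
        v, _ = distribute_flows(
            config(vd=0.15), VentilatorInputs(fio2=0.3, vt=500, rr=15),
            n_comp=20)
        assert v.sum() == pytest.approx(5.25)

    def test_closed_compartments_keep_perfusion(self):
        cfg = config(n_cc=4)
        v, q = distribute_flows(
            cfg, VentilatorInputs(fio2=0.3, vt=500, rr=15), n_comp=20)
        assert int((v == 0).sum()) == 4
        assert (q[v == 0] > 0).all()
        assert v.sum() == pytest.approx((0.5 - cfg.vd) * 15)
        assert q.sum() == pytest.approx(
            cfg.sv * 80.0 / 1000.0 * (1 - cfg.fs_anat))

    def test_zero_alveolar_ventilation(self):
        with pytest.raises(ZeroAlveolarVentilationError):
            distribute_flows(
                config(vd=0.5), VentilatorInputs(fio2=0.3, vt=500, rr=15),
                n_comp=10)

    def test_all_closed_is_bounds_error(self):
        with pytest.raises(AllCompartmentsClosedError):
            distribute_flows(
                config(n_cc=10), VentilatorInputs(fio2=0.3, vt=500, rr=15),
                n_comp=10)

    def test_resistance_quantiles_deterministic(self):
        r1 = compartment_resistances(0.2, 0.4, 50)
        r2 = compartment_resistances(0.2, 0.4, 50)
        assert (r1 == r2).all()
        assert (np.diff(r1) > 0).all()  # increasing quantiles


class TestSteadyState:
    def test_alveolar_gas_equation_oracle(self):
        """Homogeneous zero-shunt lung must satisfy PAO2 = FiO2*(PB-PH2O)
        - PaCO2/RQ within 5 mmHg (independent closed-form oracle)."""
        cfg = homogeneous(rq=0.8, vo2=250.0)
        va = 0.8 * 250 * (760 - 47) / (1000 * 40.0)  # VA giving PaCO2 = 40
        inp = VentilatorInputs(fio2=0.21, vt=(va / 14 + cfg.vd) * 1000,
                               rr=14.0, hr=75.0)
        res = simulate_steady_state(cfg, inp, n_comp=100)
        assert res.converged
        oracle = 0.21 * (760 - 47) - res.paco2 / 0.8
        assert res.pao2 == pytest.approx(oracle, abs=5.0)
        assert res.paco2 == pytest.approx(40.0, abs=1.0)

    def test_pao2_strictly_decreasing_in_ncc(self):
        inp = VentilatorInputs(fio2=0.6, vt=500, rr=16, hr=90)
        pao2 = [simulate_steady_state(
            config(vo2=100.0, sv=100.0, fs_anat=0.02, n_cc=ncc), inp,
            n_comp=100).pao2 for ncc in range(0, 100, 10)]
        assert all(a > b for a, b in zip(pao2, pao2[1:]))

    @pytest.mark.parametrize("param, values, direction", [
        ("fs_anat", [0.0, 0.1, 0.2, 0.3], "down"),   # pao2 falls with shunt
    ])
    def test_pao2_monotone_in_shunt(self, param, values, direction):
        inp = VentilatorInputs(fio2=0.4, vt=500, rr=16, hr=80)
        pao2 = [simulate_steady_state(
            config(**{param: v}), inp, n_comp=50).pao2 for v in values]
        assert all(a > b for a, b in zip(pao2, pao2[1:]))

    def test_pao2_nondecreasing_in_fio2(self):
        pao2 = [simulate_steady_state(
            config(n_cc=10), VentilatorInputs(fio2=f, vt=500, rr=16, hr=80),
            n_comp=50).pao2 for f in (0.25, 0.35, 0.5, 0.7)]
        assert all(b >= a for a, b in zip(pao2, pao2[1:]))

    def test_paco2_nonincreasing_in_ventilation(self):
        paco2 = [simulate_steady_state(
            config(), VentilatorInputs(fio2=0.3, vt=vt, rr=16, hr=80),
            n_comp=50).paco2 for vt in (350, 450, 550, 650)]
        assert all(b <= a for a, b in zip(paco2, paco2[1:]))

    def test_o2_mass_balance_at_convergence(self):
        cfg = config(sigma_fr=0.5, sigma_vr=0.4, n_cc=5, fs_anat=0.08)
        res = simulate_steady_state(
            cfg, VentilatorInputs(fio2=0.4, vt=520, rr=18, hr=85), n_comp=100)
        assert res.converged
        assert abs(res.o2_uptake - cfg.vo2) / cfg.vo2 <= 0.01

    def test_homogeneous_limit_1_vs_100_compartments(self):
        cfg = homogeneous()
        inp = VentilatorInputs(fio2=0.3, vt=500, rr=15, hr=75)
        r1 = simulate_steady_state(cfg, inp, n_comp=1)
        r100 = simulate_steady_state(cfg, inp, n_comp=100)
        assert r1.pao2 == pytest.approx(r100.pao2, abs=1e-4)
        assert r1.paco2 == pytest.approx(r100.paco2, abs=1e-4)

    def test_bit_identical_determinism(self):
        cfg = config(sigma_fr=0.4, n_cc=7)
        inp = VentilatorInputs(fio2=0.45, vt=480, rr=17, hr=92)
        a = simulate_steady_state(cfg, inp, n_comp=60)
        b = simulate_steady_state(cfg, inp, n_comp=60)
        assert a.pao2 == b.pao2 and a.paco2 == b.paco2
        assert (a._pa_o2 == b._pa_o2).all()

    def test_total_shunt_without_consumption_returns_venous(self):
        """With the whole output shunted and no O2 consumption, arterial
        blood is venous blood: PaO2 equals the initial venous PO2."""
        cfg = config(fs_anat=1.0, vo2=0.0)
        res = simulate_steady_state(
            cfg, VentilatorInputs(fio2=0.21, vt=500, rr=15, hr=75), n_comp=20)
        assert res.pao2 == pytest.approx(40.0, abs=0.01)
        assert res.cao2 == pytest.approx(res.cvo2)
        assert res.shunt_fraction_total == pytest.approx(1.0)

    def test_unsustainable_demand_raises(self):
        with pytest.raises(UnsustainableVO2Error):
            simulate_steady_state(
                config(vo2=900.0, sv=40.0, fs_anat=0.3, n_cc=15),
                VentilatorInputs(fio2=0.21, vt=400, rr=12, hr=60), n_comp=20)

    def test_arterial_content_mixing_bounds(self):
        cfg = config(sigma_fr=0.6, sigma_vr=0.5, n_cc=6, fs_anat=0.1)
        res = simulate_steady_state(
            cfg, VentilatorInputs(fio2=0.5, vt=500, rr=16, hr=80), n_comp=40)
        assert res.cvo2 <= res.cao2 <= res._cc_o2.max() + 1e-9
        assert res.shunt_fraction_total >= cfg.fs_anat
        assert 0 < res.sao2 <= 1


class TestConfigValidation:
    def test_invalid_values_rejected(self):
        with pytest.raises(DomainError):
            config(fs_anat=1.5)
        with pytest.raises(DomainError):
            config(rq=0.2)
        with pytest.raises(DomainError):
            config(sigma_fr=-0.1)
        with pytest.raises(DomainError):
            VentilatorInputs(fio2=0.1, vt=500, rr=15)
        with pytest.raises(DomainError):
            VentilatorInputs(fio2=0.3, vt=500, rr=15, pb=40.0, ph2o=47.0)

    def test_vector_round_trip(self):
        cfg = config(n_cc=3)
        assert VPConfiguration.from_vector(cfg.as_vector()) == cfg
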