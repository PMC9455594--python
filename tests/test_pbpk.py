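"""Virtual population, partitioning, clearance and whole-body ODE properties."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_compound
from pbpkflow.assumptions import IonisationType
from pbpkflow.data_collection import ConfigError
from pbpkflow.pbpk import (
    ClearanceModel,
    SimulationConfig,
    absorption_parameters,
    compute_kp_vss,
    predict_bp,
    predict_fu,
    predict_kd,
    predict_parameters,
    resolve_dose,
    select_clearance_model,
    simulate_compound,
    simulate_subject,
    wellstirred_hepatic_clearance,
    whole_liver_clint_l_h,
)
from pbpkflow.physiology import (
    TISSUES,
    generate_population,
    population_frame,
    reference_subject,
)
from pbpkflow.reporting import auc_linear_up_log_down

A = IonisationType


class TestPopulation:
    def test_seeded_determinism(self):
        a = population_frame(generate_population(15, seed=7))
        b = population_frame(generate_population(15, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_demographics_at_n_1000(self):
        subjects = generate_population(1000, seed=1)
        ages = np.array([s.age for s in subjects])
        assert ages.min() >= 20.0 and ages.max() <= 55.0
        male_fraction = np.mean([s.sex == "M" for s in subjects])
        assert abs(male_fraction - 0.5) <= 0.05
        assert all(s.bw > 0 and s.bsa > 0 and s.gfr > 0 for s in subjects)

    @pytest.mark.parametrize("n", [0, -1, 1001])
    def test_population_size_bounds(self, n):
        with pytest.raises(ValueError):
            generate_population(n, seed=1)

    def test_flow_closure(self):
        for subject in generate_population(5, seed=9):
            non_lung = sum(
                q for t, q in subject.tissue_flows.items() if t != "lung"
            )
            assert non_lung == pytest.approx(subject.cardiac_output, rel=1e-12)
            assert subject.tissue_flows["lung"] == subject.cardiac_output
            assert all(v > 0 for v in subject.tissue_volumes.values())
            assert all(q > 0 for q in subject.tissue_flows.values())


class TestPartitioning:
    def test_neutral_methods_2_and_3_coincide(self, ref_subject):
        cmpd = make_compound(ion_type=A.NEUTRAL, pka_selected=[], fu=0.2, bp=1.0)
        kp2, vss2 = compute_kp_vss(cmpd, 2, ref_subject)
        kp3, vss3 = compute_kp_vss(cmpd, 3, ref_subject)
        assert kp2 == pytest.approx(kp3)
        assert vss2 == pytest.approx(vss3)

    def test_method_1_invariant_to_pka(self, ref_subject):
        acid = make_compound(ion_type=A.MONOPROTIC_ACID, pka_selected=[4.0])
        perturbed = make_compound(ion_type=A.MONOPROTIC_ACID, pka_selected=[5.5])
        kp_a, vss_a = compute_kp_vss(acid, 1, ref_subject)
        kp_b, vss_b = compute_kp_vss(perturbed, 1, ref_subject)
        assert kp_a == kp_b and vss_a == vss_b

    def test_methods_2_3_respond_to_pka(self, ref_subject):
        base = make_compound(ion_type=A.MONOPROTIC_BASE, pka_selected=[9.0], bp=1.1)
        shifted = make_compound(ion_type=A.MONOPROTIC_BASE, pka_selected=[8.0], bp=1.1)
        for method in (2, 3):
            _, vss_a = compute_kp_vss(base, method, ref_subject)
            _, vss_b = compute_kp_vss(shifted, method, ref_subject)
            assert vss_a != pytest.approx(vss_b)

    @pytest.mark.parametrize("method", [1, 2, 3])
    @pytest.mark.parametrize(
        "kind, pkas, bp",
        [
            (A.NEUTRAL, [], 1.0),
            (A.MONOPROTIC_ACID, [4.2], 0.55),
            (A.MONOPROTIC_BASE, [9.3], 1.2),
            (A.AMPHOLYTE, [3.5, 9.5], 1.0),
            (A.DIPROTIC_BASE, [8.0, 10.0], 1.3),
        ],
    )
    def test_kp_positive_and_vss_self_consistent(self, ref_subject, method, kind, pkas, bp):
        cmpd = make_compound(ion_type=kind, pka_selected=pkas, bp=bp, fu=0.15)
        kp, vss = compute_kp_vss(cmpd, method, ref_subject)
        assert all(v > 0 for v in kp.values())
        # independent recomputation of the volume-weighted sum
        ep = max((bp - (1 - ref_subject.hct)) / ref_subject.hct, 0.0)
        vss_check = (
            ref_subject.plasma_volume
            + ref_subject.blood_cell_volume * ep
            + sum(ref_subject.tissue_volumes[t] * kp[t] for t in TISSUES)
        ) / ref_subject.bw
        assert abs(vss - vss_check) / vss_check < 1e-9

    def test_unknown_method_rejected(self, ref_subject):
        with pytest.raises(ConfigError):
            compute_kp_vss(make_compound(), 4, ref_subject)


class TestPrediction:
    def test_fu_monotone_in_lipophilicity(self):
        low = predict_fu(make_compound(logp=1.0, ion_type=A.NEUTRAL, pka_selected=[]))
        high = predict_fu(make_compound(logp=4.0, ion_type=A.NEUTRAL, pka_selected=[]))
        assert high < low
        assert 0 < high < low <= 1

    def test_acid_bp_at_least_plasma_fraction(self):
        cmpd = make_compound(ion_type=A.MONOPROTIC_ACID, pka_selected=[4.0])
        fu = predict_fu(cmpd)
        assert predict_bp(cmpd, fu, hct=0.45) >= 1 - 0.45

    def test_kd_infinite_dilution_marker(self):
        assert predict_kd(1.0, 646.0) == math.inf
        assert predict_kd(0.5, 646.0) == pytest.approx(646.0)

    def test_prediction_ignores_measured_values(self, ref_subject):
        measured = make_compound(fu=0.05, bp=2.0)
        blank = make_compound(fu=None, bp=None)
        pa = predict_parameters(measured, ref_subject)
        pb = predict_parameters(blank, ref_subject)
        assert pa.fu_pred == pb.fu_pred and pa.bp_pred == pb.bp_pred

    def test_prediction_runs_without_crash_at_full_unbound_limit(self, ref_subject):
        # strongly hydrophilic: fu prediction approaches 1, Kd must not blow up
        cmpd = make_compound(logp=-8.0, fu=None, bp=None)
        pred = predict_parameters(cmpd, ref_subject)
        assert pred.kd_hsa > 0


class TestClearanceAndDose:
    def test_model_selection(self):
        assert select_clearance_model(8.7) is ClearanceModel.HEPATIC_WELLSTIRRED
        assert select_clearance_model(None) is ClearanceModel.RENAL_ONLY

    def test_renal_clearance_product_formula(self):
        # fu = 0.2, GFR = 120 mL/min at BSA 1.73 -> CLR = 24 mL/min = 1.44 L/h
        subject = reference_subject()
        subject.gfr = 120.0
        subject.bsa = 1.73
        assert 0.2 * subject.gfr_abs_l_per_h == pytest.approx(1.44)
        subject.gfr = 100.0
        assert 1.0 * subject.gfr_abs_l_per_h == pytest.approx(6.0)  # fu=1 -> GFR

    def test_wellstirred_monotone_and_bounded(self):
        qh, fub = 90.0, 0.1
        clints = np.linspace(1.0, 5000.0, 40)
        clh = [wellstirred_hepatic_clearance(qh, fub, c) for c in clints]
        assert all(b > a for a, b in zip(clh, clh[1:]))
        assert all(c < qh for c in clh)
        assert wellstirred_hepatic_clearance(qh, fub, 1e9) == pytest.approx(qh, rel=1e-3)

    def test_clint_scaling_units(self):
        # 10 µL/min/10^6 cells, fu_hep=1, 1800 g liver, 99e6 cells/g
        expected = 10 * 99 * 1800 * 60 / 1e6
        assert whole_liver_clint_l_h(10.0, 1.0, 1800.0) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "dose, units, expected_attr",
        [(25.0, "mg", 25.0), (2.0, "mg/kg", None), (10.0, "mg.m-2", None)],
    )
    def test_resolve_dose(self, ref_subject, dose, units, expected_attr):
        resolved = resolve_dose(dose, units, ref_subject)
        if units == "mg":
            assert resolved == expected_attr
        elif units == "mg/kg":
            assert resolved == pytest.approx(dose * ref_subject.bw)
        else:
            assert resolved == pytest.approx(dose * ref_subject.bsa)

    def test_nonpositive_dose_rejected(self, ref_subject):
        with pytest.raises(ConfigError):
            resolve_dose(0.0, "mg", ref_subject)

    def test_absorption_parameters_positive_and_bounded(self):
        ka, fa = absorption_parameters(2.0)
        assert ka > 0 and 0 < fa < 1


class TestSimulationConfig:
    def test_defaults(self):
        cfg = SimulationConfig()
        assert (cfg.route, cfg.dose, cfg.dose_units) == ("oral", 100.0, "mg")
        assert (cfg.vss_method, cfg.n_subjects, cfg.duration_h) == (3, 10, 24.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"route": "inhalation"},
            {"dose": 0.0},
            {"vss_method": 4},
            {"n_subjects": 0},
            {"n_subjects": 1001},
            {"duration_h": 3.0},
            {"duration_h": 24.25},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


@pytest.fixture(scope="module")
def subjects():
    return generate_population(2, seed=5)


class TestWholeBodySimulation:
    def test_mass_balance_all_routes(self, subjects):
        for route in ("oral", "iv_bolus", "dermal"):
            cfg = SimulationConfig(route=route, dose=25.0, n_subjects=2,
                                   duration_h=24.0, seed=5)
            sim = simulate_compound(make_compound(), cfg, subjects)
            for series in sim.series:
                assert series.mass_balance_rel_err < 1e-6

    def test_dose_linearity(self, subjects):
        cmpd = make_compound()
        cfg1 = SimulationConfig(dose=10.0, n_subjects=2, seed=5)
        cfg2 = SimulationConfig(dose=20.0, n_subjects=2, seed=5)
        sim1 = simulate_compound(cmpd, cfg1, subjects)
        sim2 = simulate_compound(cmpd, cfg2, subjects)
        for s1, s2 in zip(sim1.series, sim2.series):
            for tissue in s1.conc:
                c1, c2 = s1.conc[tissue], s2.conc[tissue]
                mask = c1 > 1e-6 * c1.max() if c1.max() > 0 else np.zeros_like(c1, bool)
                assert np.allclose(c2[mask], 2.0 * c1[mask], rtol=1e-5)

    def test_iv_auc_equals_dose_over_clearance(self, subjects):
        cmpd = make_compound(clint=15.0, fu=0.2, bp=1.0)
        cfg = SimulationConfig(route="iv_bolus", dose=25.0, n_subjects=2,
                               duration_h=168.0, seed=5)
        sim = simulate_compound(cmpd, cfg, subjects)
        ledger = sim.ledger.set_index("subject_id")
        for series in sim.series:
            t, c = series.time_h, series.conc["plasma"]
            auc = auc_linear_up_log_down(t, c)
            # closed tail from the terminal log-slope
            kel = (np.log(c[-10]) - np.log(c[-1])) / (t[-1] - t[-10])
            auc_inf = auc + c[-1] / kel
            row = ledger.loc[series.subject_id]
            expected = row["dose_mg"] * 1000.0 / row["cl_tot"]  # ng·h/mL
            assert abs(auc_inf - expected) / expected < 0.01

    def test_renal_only_slower_than_hepatic(self, subjects):
        base = make_compound(clint=None, fu=0.2, bp=1.0)
        matched = make_compound(clint=10.0, fu=0.2, bp=1.0)
        cfg = SimulationConfig(dose=25.0, n_subjects=2, duration_h=48.0, seed=5)
        sim_renal = simulate_compound(base, cfg, subjects)
        sim_hep = simulate_compound(matched, cfg, subjects)
        assert sim_renal.clearance_model is ClearanceModel.RENAL_ONLY
        assert sim_hep.clearance_model is ClearanceModel.HEPATIC_WELLSTIRRED
        assert (sim_renal.ledger["cl_tot"] < sim_hep.ledger["cl_tot"]).all()
        assert (sim_renal.ledger["cl_h"] == 0).all()

    def test_seeded_run_byte_identical(self, subjects):
        cmpd = make_compound()
        cfg = SimulationConfig(dose=25.0, n_subjects=2, seed=5)
        sim_a = simulate_compound(cmpd, cfg, subjects)
        sim_b = simulate_compound(cmpd, cfg, subjects)
        for sa, sb in zip(sim_a.series, sim_b.series):
            for tissue in sa.conc:
                assert np.array_equal(sa.conc[tissue], sb.conc[tissue])
        pd.testing.assert_frame_equal(sim_a.ledger, sim_b.ledger)

    def test_equilibrium_without_elimination(self, subjects):
        # IV dose, no clearance: the linear system settles at
        # C_blood = dose / (blood volume + sum V_t * Kp_blood_t)
        from pbpkflow.pbpk import _IDX, _N_STATES, _rhs_factory
        from scipy.integrate import solve_ivp

        subject = subjects[0]
        kp_blood = {t: 1.0 for t in TISSUES}
        rhs = _rhs_factory(subject, kp_blood, "iv_bolus", 0, 0, 0,
                           cl_uint=0.0, fu_blood=0.1, clr_blood=0.0,
                           infusion_rate=0.0)
        y0 = np.zeros(_N_STATES)
        dose = 25.0
        y0[_IDX["venous"]] = dose
        sol = solve_ivp(rhs, (0, 500.0), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        v_total = subject.blood_volume + sum(subject.tissue_volumes.values())
        c_eq = dose / v_total
        c_ven = sol.y[_IDX["venous"], -1] / (subject.blood_volume * 2 / 3)
        assert abs(c_ven - c_eq) / c_eq < 1e-3

    def test_zero_concentration_before_dosing_tissues_nonnegative(self, subjects):
        cfg = SimulationConfig(dose=25.0, n_subjects=1, seed=5)
        sim = simulate_compound(make_compound(), cfg, subjects[:1])
        for series in sim.series:
            for conc in series.conc.values():
                assert conc[0] == 0.0
                assert (conc >= 0).all()

    def test_per_compound_dose_and_units_override(self, subjects):
        cmpd = make_compound(dose=2.0, dose_units="mg/kg")
        cfg = SimulationConfig(dose=100.0, n_subjects=1, seed=5)
        _, row = simulate_subject(cmpd, cfg, subjects[0])
        assert row["dose_mg"] == pytest.approx(2.0 * subjects[0].bw)
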