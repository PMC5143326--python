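"""Generator contracts: determinism, noise-free identities, censoring,
and the intervention / organ-distribution constructions."""

import dataclasses

import numpy as np
import pytest

from ccn2pk import (BolusScenario, InfusionScenario, SPRScenario,
                    biexp_concentration, clearance_report,
                    fit_two_compartment, organ_uptake_fraction,
                    simulate_bolus_curve, simulate_infusion_steady_state,
                    simulate_intervention_pair, simulate_organ_distribution,
                    simulate_sensorgram, simulate_spr_equilibrium)
from ccn2pk.models import TwoCompartmentMacro


class TestBolusGenerator:
    def test_noise_free_initial_concentration_is_dose_over_v1(self):
        # dose 25 000 pmol/kg over V1 = 454 mL/kg -> C(0) ~ 55.1 pmol/mL
        sc = BolusScenario(noise_cv=0.0, seed=0)
        assert sc.macro.c0 == pytest.approx(25_000.0 / 454.0)
        assert sc.macro.c0 == pytest.approx(55.1, abs=0.05)
        curve = simulate_bolus_curve(sc)
        expected = biexp_concentration(sc.macro, curve.time_min)
        np.testing.assert_allclose(curve.conc_pmol_per_ml, expected, rtol=1e-12)

    def test_same_seed_reproduces_dataset_exactly(self):
        a = simulate_bolus_curve(BolusScenario(seed=42))
        b = simulate_bolus_curve(BolusScenario(seed=42))
        np.testing.assert_array_equal(a.conc_pmol_per_ml, b.conc_pmol_per_ml)
        np.testing.assert_array_equal(a.censored, b.censored)
        c = simulate_bolus_curve(BolusScenario(seed=43))
        assert not np.array_equal(a.conc_pmol_per_ml, c.conc_pmol_per_ml)

    def test_design_shape_one_row_per_animal_per_time(self):
        sc = BolusScenario(seed=1)
        curve = simulate_bolus_curve(sc)
        assert len(curve) == len(sc.sample_times) * sc.animals_per_time
        assert len(np.unique(curve.subject)) == len(curve)

    def test_below_lod_observations_are_censored_at_lod(self):
        # force censoring with an artificially high detection limit
        sc = BolusScenario(seed=7, lod=5.0)
        curve = simulate_bolus_curve(sc)
        assert curve.censored.any()
        assert np.all(curve.conc_pmol_per_ml[~curve.censored] >= sc.lod)
        assert np.all(curve.conc_pmol_per_ml[curve.censored] == sc.lod)

    def test_degenerate_rate_constants_rejected(self):
        macro = TwoCompartmentMacro(A=40.0, B=15.0, alpha=0.03000001, beta=0.03)
        with pytest.raises(ValueError, match="ill-posed"):
            BolusScenario(macro=macro, seed=0)

    @pytest.mark.parametrize("kwargs", [
        {"dose_per_kg": -1.0},
        {"sample_times": (5.0, 2.0)},
        {"sample_times": (0.0, 2.0)},
        {"noise_cv": -0.1},
        {"animals_per_time": 0},
    ])
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BolusScenario(seed=0, **kwargs)


class TestInfusionGenerator:
    def test_noise_free_arterial_is_rate_over_clearance(self, noise_free_infusion):
        ds = simulate_infusion_steady_state(noise_free_infusion)
        np.testing.assert_allclose(ds.arterial_conc, 54.0 / 45.0, rtol=1e-12)

    def test_noise_free_round_trip_recovers_scenario_physiology(
            self, noise_free_infusion):
        ds = simulate_infusion_steady_state(noise_free_infusion)
        rpt = clearance_report(ds)
        sc = noise_free_infusion
        assert rpt.cl_total == pytest.approx(sc.total_clearance, rel=1e-9)
        assert rpt.cl_renal == pytest.approx(sc.renal_clearance, rel=1e-9)
        assert rpt.gfr == pytest.approx(sc.gfr, rel=1e-9)
        assert rpt.erpf == pytest.approx(sc.erpf, rel=1e-9)
        assert rpt.urinary_excretion_cl == pytest.approx(
            sc.urinary_excretion_cl, rel=1e-9)

    def test_noise_free_urine_plasma_inulin_ratio(self, noise_free_infusion):
        # GFR 9.0 at urine flow 0.05 -> U/P = 180
        ds = simulate_infusion_steady_state(noise_free_infusion)
        assert ds.urine_inulin / ds.plasma_inulin == pytest.approx(180.0)

    def test_steady_state_mass_balance_is_exact(self, noise_free_infusion):
        ds = simulate_infusion_steady_state(noise_free_infusion)
        assert float(np.mean(ds.arterial_conc)) * noise_free_infusion.total_clearance \
            == pytest.approx(noise_free_infusion.infusion_rate, rel=1e-12)

    def test_renal_clearance_exceeding_erpf_rejected(self):
        with pytest.raises(ValueError):
            InfusionScenario(renal_clearance=31.0, erpf=30.0, total_clearance=45.0)

    def test_determinism(self):
        a = simulate_infusion_steady_state(InfusionScenario(seed=9))
        b = simulate_infusion_steady_state(InfusionScenario(seed=9))
        np.testing.assert_array_equal(a.arterial_conc, b.arterial_conc)
        assert a.renal_vein_conc == b.renal_vein_conc


class TestSPRGenerator:
    def test_half_saturation_and_baseline(self):
        sc = SPRScenario(kd=116.0, rmax=10.0, concentrations=(0.0, 116.0),
                         noise_sd=0.0, seed=0)
        ds = simulate_spr_equilibrium(sc)
        assert ds.responses[0] == 0.0
        assert ds.responses[1] == pytest.approx(5.0)

    def test_langmuir_value_at_top_concentration(self):
        # Rmax 10, Kd 116, C 200 -> 10*200/316
        sc = SPRScenario(kd=116.0, rmax=10.0, concentrations=(200.0,),
                         noise_sd=0.0, seed=0)
        ds = simulate_spr_equilibrium(sc)
        assert ds.responses[0] == pytest.approx(6.3291, abs=1e-3)

    def test_determinism(self):
        a = simulate_spr_equilibrium(SPRScenario(seed=3))
        b = simulate_spr_equilibrium(SPRScenario(seed=3))
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_sensorgram_plateau_reaches_req(self, noise_free_spr):
        tr = simulate_sensorgram(noise_free_spr, 100.0)
        req = noise_free_spr.rmax * 100.0 / (noise_free_spr.kd + 100.0)
        stop_idx = np.searchsorted(tr.times, tr.injection_stop)
        assert tr.responses[stop_idx - 1] == pytest.approx(req, rel=1e-3)

    def test_sensorgram_zero_concentration_is_flat_zero(self, noise_free_spr):
        tr = simulate_sensorgram(noise_free_spr, 0.0)
        np.testing.assert_allclose(tr.responses, 0.0, atol=1e-12)

    def test_dissociation_decay_rate_matches_ka_times_kd(self, noise_free_spr):
        # log-linear regression on the noise-free dissociation phase
        tr = simulate_sensorgram(noise_free_spr, 50.0)
        m = tr.times > tr.injection_stop
        slope = np.polyfit(tr.times[m] - tr.injection_stop,
                           np.log(tr.responses[m]), 1)[0]
        assert -slope == pytest.approx(noise_free_spr.ka * noise_free_spr.kd,
                                       rel=1e-9)


class TestInterventionPair:
    def test_identity_scales_with_shared_seed_reproduce_control(self):
        sc = BolusScenario(seed=21)
        ctrl, trt = simulate_intervention_pair(sc, 1.0, 1.0,
                                               treated_seed=sc.seed)
        np.testing.assert_array_equal(ctrl.conc_pmol_per_ml, trt.conc_pmol_per_ml)

    def test_default_treated_arm_uses_independent_animals(self):
        sc = BolusScenario(seed=21)
        ctrl, trt = simulate_intervention_pair(sc, 1.0, 1.0)
        assert not np.array_equal(ctrl.conc_pmol_per_ml, trt.conc_pmol_per_ml)

    def test_pure_volume_change_is_parallel_shift(self):
        # V1 scaled by 1/7 multiplies every concentration by 7
        sc = BolusScenario(noise_cv=0.0, seed=2)
        ctrl, trt = simulate_intervention_pair(sc, v1_scale=1.0 / 7.0)
        np.testing.assert_allclose(
            trt.conc_pmol_per_ml / ctrl.conc_pmol_per_ml, 7.0, rtol=1e-10)

    def test_volume_scale_recovered_by_fitting_noise_free_arms(self):
        sc = BolusScenario(noise_cv=0.0, seed=2)
        ctrl, trt = simulate_intervention_pair(sc, v1_scale=0.12)
        fit_c = fit_two_compartment(ctrl, sc.dose_per_kg)
        fit_t = fit_two_compartment(trt, sc.dose_per_kg)
        assert 100.0 * (1.0 - fit_t.v1 / fit_c.v1) == pytest.approx(88.0, abs=1e-6)

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            simulate_intervention_pair(BolusScenario(seed=0), v1_scale=0.0)


class TestOrganDistribution:
    def test_round_trip_recovers_input_fractions(self):
        fractions = {"liver": 0.30, "kidney": 0.06, "lung": 0.01}
        weights = {"liver": 1.25, "kidney": 0.30, "lung": 0.15}
        ds = simulate_organ_distribution(fractions, weights, dose_total=625.0)
        for organ, conc, w in zip(ds.organs, ds.tissue_conc, ds.organ_weights):
            pct = organ_uptake_fraction(conc, w, ds.dose_total)
            assert pct == pytest.approx(100.0 * fractions[organ], rel=1e-12)

    def test_liver_concentration_example(self):
        # 30 %ID in a 1.25 g liver after 625 pmol -> 150 pmol/g
        ds = simulate_organ_distribution({"liver": 0.30}, {"liver": 1.25}, 625.0)
        assert ds.tissue_conc[0] == pytest.approx(150.0)

    def test_zero_fraction_gives_zero_concentration(self):
        ds = simulate_organ_distribution({"spleen": 0.0}, {"spleen": 0.1}, 100.0)
        assert ds.tissue_conc[0] == 0.0

    def test_fractions_over_unity_rejected(self):
        with pytest.raises(ValueError):
            simulate_organ_distribution({"a": 0.7, "b": 0.5}, {"a": 1, "b": 1}, 10.0)
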