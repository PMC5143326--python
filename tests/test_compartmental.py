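"""Two-compartment disposition: forward model, parameter algebra,
curve stripping, fitting and intervention comparisons."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccn2pk import (BolusScenario, biexp_concentration,
                    curve_strip_initial_estimates, derive_seeds,
                    estimate_volume_shift, fit_two_compartment, fold_change,
                    macro_to_micro, micro_to_macro, simulate_bolus_curve,
                    simulate_intervention_pair)
from ccn2pk.models import TwoCompartmentMacro, TwoCompartmentMicro

from conftest import make_curve


macros = st.builds(
    TwoCompartmentMacro,
    A=st.floats(0.5, 100.0),
    B=st.floats(0.5, 100.0),
    alpha=st.floats(0.1, 2.0),
    beta=st.floats(0.001, 0.05),
)


class TestForwardModel:
    def test_time_zero_is_sum_of_intercepts(self, textbook_macro):
        assert biexp_concentration(textbook_macro, 0.0) == pytest.approx(55.0)

    def test_textbook_value_at_ten_minutes(self, textbook_macro):
        # 40 e^-3 + 15 e^-0.3
        assert biexp_concentration(textbook_macro, 10.0) == pytest.approx(
            13.1038, abs=1e-3)

    def test_long_time_limit_decays_to_zero(self, textbook_macro):
        assert biexp_concentration(textbook_macro, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_negative_time_rejected(self, textbook_macro):
        with pytest.raises(ValueError):
            biexp_concentration(textbook_macro, -1.0)


class TestParameterAlgebra:
    def test_textbook_micro_constants(self, textbook_macro):
        micro = macro_to_micro(textbook_macro, dose=1000.0)
        assert micro.k21 == pytest.approx(0.1036364, abs=1e-6)
        assert micro.k10 == pytest.approx(0.0868421, abs=1e-6)
        assert micro.k12 == pytest.approx(0.1395215, abs=1e-6)
        assert micro.v1 == pytest.approx(1000.0 / 55.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(macro=macros, dose=st.floats(10.0, 1e5))
    def test_round_trip_and_rate_identities(self, macro, dose):
        micro = macro_to_micro(macro, dose)
        # invariant identities of the eigenvalue decomposition
        assert micro.k10 * micro.k21 == pytest.approx(
            macro.alpha * macro.beta, rel=1e-9)
        assert micro.k10 + micro.k12 + micro.k21 == pytest.approx(
            macro.alpha + macro.beta, rel=1e-9)
        back = micro_to_macro(micro, dose)
        for name in ("A", "B", "alpha", "beta"):
            assert getattr(back, name) == pytest.approx(
                getattr(macro, name), rel=1e-10)

    def test_one_compartment_limit(self):
        macro = TwoCompartmentMacro(A=50.0, B=0.0, alpha=0.3, beta=0.03)
        micro = macro_to_micro(macro, dose=1000.0)
        assert micro.k21 == pytest.approx(0.03)
        assert micro.k10 == pytest.approx(0.3)
        assert micro.k12 == pytest.approx(0.0, abs=1e-15)

    def test_zero_intercepts_rejected(self):
        macro = TwoCompartmentMacro(A=0.0, B=0.0, alpha=0.3, beta=0.03)
        with pytest.raises(ValueError):
            macro_to_micro(macro, dose=100.0)

    def test_rate_ordering_enforced_at_construction(self):
        with pytest.raises(ValueError):
            TwoCompartmentMacro(A=1.0, B=1.0, alpha=0.03, beta=0.3)


class TestCurveStripping:
    def _noise_free_curve(self, macro, times):
        return make_curve(times, biexp_concentration(macro, np.asarray(times)))

    def test_recovers_generating_macro_within_5_percent(self, textbook_macro):
        times = np.geomspace(0.5, 80.0, 12)
        est = curve_strip_initial_estimates(self._noise_free_curve(
            textbook_macro, times))
        for name in ("A", "B", "alpha", "beta"):
            assert getattr(est, name) == pytest.approx(
                getattr(textbook_macro, name), rel=0.05)

    def test_shuffled_input_gives_same_result(self, textbook_macro):
        times = np.geomspace(0.5, 80.0, 12)
        curve = self._noise_free_curve(textbook_macro, times)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(times))
        shuffled = make_curve(curve.time_min[perm], curve.conc_pmol_per_ml[perm])
        a = curve_strip_initial_estimates(curve)
        b = curve_strip_initial_estimates(shuffled)
        assert (a.A, a.B, a.alpha, a.beta) == (b.A, b.B, b.alpha, b.beta)

    def test_monoexponential_input_flagged_degenerate(self):
        times = np.linspace(1.0, 60.0, 10)
        conc = 20.0 * np.exp(-0.05 * times)
        est = curve_strip_initial_estimates(make_curve(times, conc))
        assert est.B == pytest.approx(20.0, rel=0.01)
        assert est.beta == pytest.approx(0.05, rel=0.01)
        assert est.A < 1e-3 * est.B  # distribution phase carries no signal

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            curve_strip_initial_estimates(make_curve([1, 2, 3], [3, 2, 1]))


class TestTwoCompartmentFit:
    def test_zero_noise_oracle_recovery(self, noise_free_bolus):
        curve = simulate_bolus_curve(noise_free_bolus)
        fit = fit_two_compartment(curve, noise_free_bolus.dose_per_kg)
        true = noise_free_bolus.macro
        for name in ("A", "B", "alpha", "beta"):
            assert getattr(fit.macro, name) == pytest.approx(
                getattr(true, name), rel=1e-6)
        assert fit.v1 == pytest.approx(454.0, rel=1e-6)
        assert fit.cl_initial == pytest.approx(120.0, rel=1e-6)
        assert fit.t_half_initial == pytest.approx(math.log(2) * 454.0 / 120.0,
                                                   rel=1e-6)

    def test_dose_conservation_identity(self, noise_free_bolus):
        curve = simulate_bolus_curve(noise_free_bolus)
        fit = fit_two_compartment(curve, noise_free_bolus.dose_per_kg)
        assert fit.cl_total * fit.auc == pytest.approx(
            noise_free_bolus.dose_per_kg, rel=1e-6)

    def test_alpha_beta_ordering_always_returned(self):
        for seed in derive_seeds(99, 10):
            curve = simulate_bolus_curve(BolusScenario(seed=seed))
            fit = fit_two_compartment(curve, 25_000.0)
            assert fit.macro.alpha > fit.macro.beta

    def test_censored_points_excluded_and_counted(self):
        sc = BolusScenario(seed=7, lod=5.0)
        curve = simulate_bolus_curve(sc)
        n_cens = int(curve.censored.sum())
        assert n_cens > 0
        fit = fit_two_compartment(curve, sc.dose_per_kg)
        assert fit.n_censored == n_cens
        assert fit.n_used == len(curve) - n_cens

    def test_noise_never_improves_median_v1_recovery(self):
        # estimator degradation must be monotone in assay CV
        medians = []
        for cv in (0.0, 0.05, 0.10):
            errs = []
            for seed in derive_seeds(7, 30):
                sc = BolusScenario(noise_cv=cv, seed=seed)
                fit = fit_two_compartment(simulate_bolus_curve(sc),
                                          sc.dose_per_kg)
                errs.append(abs(fit.v1 - 454.0))
            medians.append(float(np.median(errs)))
        assert medians[0] <= medians[1] <= medians[2]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_two_compartment(make_curve([1, 2, 3, 4], [40, 30, 20, 10]), 100.0)


class TestInterventionComparisons:
    def test_identical_fits_give_zero_shift_and_zero_ratio_cv(self, noise_free_bolus):
        curve = simulate_bolus_curve(noise_free_bolus)
        fit = fit_two_compartment(curve, noise_free_bolus.dose_per_kg)
        reduction, cv = estimate_volume_shift(fit, fit)
        assert reduction == pytest.approx(0.0, abs=1e-12)
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_volume_only_change_small_ratio_cv(self):
        sc = BolusScenario(noise_cv=0.0, seed=5)
        ctrl, trt = simulate_intervention_pair(sc, v1_scale=0.12)
        fit_c = fit_two_compartment(ctrl, sc.dose_per_kg)
        fit_t = fit_two_compartment(trt, sc.dose_per_kg)
        reduction, cv = estimate_volume_shift(fit_c, fit_t)
        assert reduction == pytest.approx(88.0, abs=1e-6)
        assert cv < 1e-6  # parallel shift: constant ratio at all times

    def test_elimination_only_change_flagged_by_ratio_cv(self):
        sc = BolusScenario(noise_cv=0.0, seed=5)
        ctrl, trt = simulate_intervention_pair(sc, elimination_scale=0.1)
        fit_c = fit_two_compartment(ctrl, sc.dose_per_kg)
        fit_t = fit_two_compartment(trt, sc.dose_per_kg)
        reduction, cv = estimate_volume_shift(fit_c, fit_t)
        assert abs(reduction) < 1.0    # V1 essentially unchanged
        assert cv > 0.2                # curves are far from parallel

    def test_fold_change_identical_arms_is_unity(self):
        curve = make_curve([10, 12, 14], [5.0, 4.0, 3.0])
        out = fold_change(curve, curve, (10, 15))
        assert out["ratio"] == pytest.approx(1.0)

    def test_fold_change_exact_scaling(self):
        ctrl = make_curve([10, 12, 14], [5.0, 4.0, 3.0])
        trt = make_curve([10, 12, 14], [35.0, 28.0, 21.0], arm="treated")
        for window in [(10, 15), (9, 13)]:
            assert fold_change(ctrl, trt, window)["ratio"] == pytest.approx(7.0)

    def test_t_statistic_matches_textbook_pooled_formula(self):
        ctrl_vals = [5.1, 4.8, 5.5, 5.0, 4.9]
        trt_vals = [24.0, 26.5, 25.2, 23.1, 27.8]
        ctrl = make_curve([12.0] * 5, ctrl_vals)
        trt = make_curve([12.0] * 5, trt_vals, arm="treated")
        out = fold_change(ctrl, trt, (10, 15))
        # independent textbook computation: pooled-variance two-sample t
        x, y = np.log(trt_vals), np.log(ctrl_vals)
        sp2 = ((len(x) - 1) * np.var(x, ddof=1)
               + (len(y) - 1) * np.var(y, ddof=1)) / (len(x) + len(y) - 2)
        t_hand = (np.mean(x) - np.mean(y)) / math.sqrt(
            sp2 * (1.0 / len(x) + 1.0 / len(y)))
        assert out["t_statistic"] == pytest.approx(t_hand, rel=1e-12)
        assert out["p_value"] < 0.001

    def test_empty_window_rejected(self):
        curve = make_curve([1.0, 2.0], [5.0, 4.0])
        with pytest.raises(ValueError):
            fold_change(curve, curve, (10, 15))
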