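"""Synthetic-data generators emulating the animal and biosensor experiments.

Three experiment families are emulated:

* **Mouse IV bolus with destructive sampling** — each animal contributes a
  single plasma sample; the true curve is the two-compartment biexponential;
  assay error is multiplicative lognormal with a fixed CV (mean-one, so
  noisy concentrations are unbiased); values below the ELISA detection
  limit are censored.
* **Rat steady-state infusion** — arterial / renal-vein / urine tracer
  concentrations and inulin/PAH marker concentrations constructed so that
  the steady-state clearance formulae reproduce the scenario's physiology
  exactly in the noise-free limit.
* **SPR binding** — 1:1 Langmuir equilibrium responses over a dilution
  series (additive Gaussian instrument noise) and, for kinetic work,
  exponential association/dissociation sensorgrams.

Every scenario carries an explicit integer seed; there is no hidden global
RNG state, and identical scenarios produce identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from . import defaults
from .compartmental import (DEGENERACY_TOL, biexp_concentration,
                            macro_to_micro, micro_to_macro)
from .models import (OrganDataset, PlasmaCurve, SensorgramTrace,
                     SPREquilibriumDataset, SteadyStateDataset,
                     TwoCompartmentMacro)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


# --------------------------------------------------------------------------
# Scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BolusScenario:
    """Design of one IV-bolus plasma-disappearance experiment."""

    dose_per_kg: float = defaults.MOUSE_DOSE_PMOL_PER_KG
    macro: TwoCompartmentMacro = None  # type: ignore[assignment]
    sample_times: Sequence[float] = defaults.MOUSE_SAMPLE_TIMES_MIN
    animals_per_time: int = defaults.ANIMALS_PER_TIME
    noise_cv: float = defaults.ASSAY_CV
    lod: float = defaults.ELISA_LOD_PMOL_PER_ML
    seed: int = 0
    arm: str = "control"

    def __post_init__(self) -> None:
        if self.macro is None:
            object.__setattr__(self, "macro",
                               defaults.default_mouse_macro(self.dose_per_kg))
        if self.dose_per_kg <= 0:
            raise ValueError("dose_per_kg must be positive")
        object.__setattr__(self, "sample_times",
                           tuple(float(t) for t in self.sample_times))
        times = np.asarray(self.sample_times, dtype=float)
        if np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly positive and sorted")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.animals_per_time < 1:
            raise ValueError("animals_per_time must be >= 1")
        rel_sep = (self.macro.alpha - self.macro.beta) / self.macro.alpha
        if rel_sep < DEGENERACY_TOL:
            raise ValueError("alpha ~ beta: ill-posed two-compartment scenario")


@dataclass(frozen=True)
class InfusionScenario:
    """Design of one steady-state infusion clearance experiment."""

    infusion_rate: float = defaults.RAT_INFUSION_RATE
    total_clearance: float = defaults.RAT_CL_TOTAL
    renal_clearance: float = defaults.RAT_CL_RENAL
    erpf: float = defaults.RAT_ERPF
    gfr: float = defaults.RAT_GFR
    urine_flow: float = defaults.RAT_URINE_FLOW
    urinary_excretion_cl: float = 1.0
    n_arterial: int = defaults.N_ARTERIAL_SAMPLES
    noise_cv: float = defaults.ASSAY_CV
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("infusion_rate", "total_clearance", "renal_clearance",
                     "erpf", "gfr", "urine_flow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.renal_clearance > self.total_clearance:
            raise ValueError("renal_clearance cannot exceed total_clearance")
        if self.renal_clearance > self.erpf:
            raise ValueError("renal_clearance cannot exceed ERPF")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass(frozen=True)
class SPRScenario:
    """Design of an SPR binding experiment (equilibrium series or kinetics)."""

    kd: float = defaults.SPR_KD_FULL_LENGTH_NM
    rmax: float = defaults.SPR_RMAX_PG_MM2
    concentrations: Sequence[float] = defaults.SPR_CONCENTRATIONS_NM
    noise_sd: float = defaults.SPR_NOISE_SD
    ka: float = defaults.SPR_KA_PER_NM_MIN
    t_assoc: float = defaults.SPR_T_ASSOC_MIN
    t_dissoc: float = defaults.SPR_T_DISSOC_MIN
    seed: int = 0
    ligand_label: str = "full-length"

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations",
                           tuple(float(c) for c in self.concentrations))
        if self.kd <= 0 or self.rmax <= 0:
            raise ValueError("kd and rmax must be positive")
        if np.any(np.asarray(self.concentrations, dtype=float) < 0):
            raise ValueError("concentrations must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def koff(self) -> float:
        return self.ka * self.kd


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def simulate_bolus_curve(scenario: BolusScenario) -> PlasmaCurve:
    """Simulate a destructively sampled plasma disappearance curve.

    One observation per animal per sampling time; each animal receives an
    independent multiplicative lognormal assay error. Observations whose
    noisy value falls below the LOD are flagged censored and recorded at
    the LOD value.
    """
    rng = np.random.default_rng(scenario.seed)
    times = np.repeat(np.asarray(scenario.sample_times, dtype=float),
                      scenario.animals_per_time)
    true = biexp_concentration(scenario.macro, times)
    noisy = true * _lognormal_factors(rng, scenario.noise_cv, len(times))
    censored = noisy < scenario.lod
    conc = np.where(censored, scenario.lod, noisy)
    subjects = np.array([f"{scenario.arm}-m{i + 1:03d}" for i in range(len(times))],
                        dtype=object)
    return PlasmaCurve(subject=subjects, time_min=times, conc_pmol_per_ml=conc,
                       censored=censored, arm=scenario.arm)


def simulate_infusion_steady_state(scenario: InfusionScenario) -> SteadyStateDataset:
    """Simulate one rat steady-state infusion dataset.

    Noise-free construction (exact round trip with the clearance formulae):

    * arterial concentration  Ca = rate / CL_total
    * renal-vein concentration back-solved from the extraction equation,
      Cv = Ca (ERPF - CL_renal) / (ERPF - Vdot)
    * inulin and PAH urine/plasma ratios set to GFR/Vdot and ERPF/Vdot
      (marker plasma levels use an arbitrary unit of 1)
    * urine tracer concentration set so the urinary excretion clearance
      U * Vdot / Ca equals the scenario value.

    Multiplicative lognormal noise is then applied independently to every
    concentration; the urine flow is treated as measured exactly
    (volumetric collection).
    """
    rng = np.random.default_rng(scenario.seed)
    ca = scenario.infusion_rate / scenario.total_clearance
    vdot = scenario.urine_flow
    if scenario.erpf <= vdot:
        raise ValueError("ERPF must exceed urine flow")
    cv_renal = ca * (scenario.erpf - scenario.renal_clearance) / (scenario.erpf - vdot)
    plasma_inulin = 1.0
    urine_inulin = scenario.gfr / vdot * plasma_inulin
    plasma_pah = 1.0
    urine_pah = scenario.erpf / vdot * plasma_pah
    urine_ccn2 = scenario.urinary_excretion_cl * ca / vdot

    f = _lognormal_factors(rng, scenario.noise_cv, scenario.n_arterial + 6)
    arterial = ca * f[:scenario.n_arterial]
    k = scenario.n_arterial
    return SteadyStateDataset(
        infusion_rate=scenario.infusion_rate,
        arterial_conc=arterial,
        renal_vein_conc=cv_renal * f[k],
        urine_flow=vdot,
        urine_ccn2=urine_ccn2 * f[k + 1],
        plasma_inulin=plasma_inulin * f[k + 2],
        urine_inulin=urine_inulin * f[k + 3],
        plasma_pah=plasma_pah * f[k + 4],
        urine_pah=urine_pah * f[k + 5],
    )


def simulate_spr_equilibrium(scenario: SPRScenario) -> SPREquilibriumDataset:
    """Simulate equilibrium responses R = Rmax C/(Kd + C) + N(0, sd)."""
    rng = np.random.default_rng(scenario.seed)
    conc = np.asarray(scenario.concentrations, dtype=float)
    resp = scenario.rmax * conc / (scenario.kd + conc)
    resp = resp + rng.normal(0.0, scenario.noise_sd, size=len(conc)) \
        if scenario.noise_sd > 0 else resp.copy()
    return SPREquilibriumDataset(concentrations=conc, responses=resp,
                                 ligand_label=scenario.ligand_label)


def simulate_sensorgram(scenario: SPRScenario, concentration: float,
                        dt: float = 0.005) -> SensorgramTrace:
    """Simulate a 1:1 kinetic sensorgram at one analyte concentration.

    Association: R(t) = Req (1 - e^(-(ka C + koff) t)) with
    Req = Rmax C/(Kd + C) and koff = ka Kd; dissociation: exponential decay
    at rate koff from the response at injection stop. Additive Gaussian
    noise (scenario.noise_sd) per point.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng((scenario.seed, int(round(concentration * 1e3))))
    koff = scenario.koff
    kobs = scenario.ka * concentration + koff
    req = scenario.rmax * concentration / (scenario.kd + concentration)
    t_stop = scenario.t_assoc
    t = np.arange(0.0, t_stop + scenario.t_dissoc + 0.5 * dt, dt)
    assoc = t <= t_stop
    r = np.empty_like(t)
    r[assoc] = req * (1.0 - np.exp(-kobs * t[assoc]))
    r_stop = req * (1.0 - math.exp(-kobs * t_stop))
    r[~assoc] = r_stop * np.exp(-koff * (t[~assoc] - t_stop))
    if scenario.noise_sd > 0:
        r = r + rng.normal(0.0, scenario.noise_sd, size=len(t))
    return SensorgramTrace(times=t, responses=r, concentration=concentration,
                           injection_stop=t_stop)


# --------------------------------------------------------------------------
# Interventions
# --------------------------------------------------------------------------

def transform_macro(macro: TwoCompartmentMacro, dose: float,
                    v1_scale: float = 1.0,
                    elimination_scale: float = 1.0) -> TwoCompartmentMacro:
    """Scale the initial volume and/or elimination constant of a disposition.

    Works in micro space: v1 -> v1 * v1_scale, k10 -> k10 * elimination_scale
    with k12, k21 untouched, then converts back. A pure volume change leaves
    the curve shape fixed and multiplies every concentration by 1/v1_scale
    (parallel shift on the log scale).
    """
    if v1_scale <= 0 or elimination_scale <= 0:
        raise ValueError("scales must be positive")
    if v1_scale == 1.0 and elimination_scale == 1.0:
        return macro
    micro = macro_to_micro(macro, dose)
    micro = replace(micro, v1=micro.v1 * v1_scale,
                    k10=micro.k10 * elimination_scale)
    return micro_to_macro(micro, dose)


def simulate_intervention_pair(control: BolusScenario,
                               v1_scale: float = 1.0,
                               elimination_scale: float = 1.0,
                               treated_seed: Optional[int] = None,
                               ) -> Tuple[PlasmaCurve, PlasmaCurve]:
    """Simulate a paired control / pre-treated bolus experiment.

    The treated arm shares the control design but its disposition has v1
    multiplied by ``v1_scale`` and the elimination constant k10 by
    ``elimination_scale``. Treated animals are distinct animals, so by
    default their assay errors are drawn independently (treated seed derived
    from the control seed); pass ``treated_seed=control.seed`` to share the
    noise stream, in which case identical scales reproduce the control
    curve exactly.
    """
    macro_t = transform_macro(control.macro, control.dose_per_kg,
                              v1_scale, elimination_scale)
    if treated_seed is None:
        treated_seed = int(np.random.SeedSequence(control.seed).spawn(1)[0]
                           .generate_state(1)[0] % (2 ** 31))
    treated = replace(control, macro=macro_t, seed=treated_seed, arm="treated")
    return simulate_bolus_curve(control), simulate_bolus_curve(treated)


def calibrate_elimination_scale(macro: TwoCompartmentMacro, dose: float,
                                target_fold: float = defaults.RAP_TARGET_FOLD,
                                window: Tuple[float, float] = defaults.RAP_WINDOW_MIN,
                                sample_times: Optional[Sequence[float]] = None,
                                ) -> float:
    """Elimination-scale factor producing a given concentration fold-change.

    Solves for the factor s such that scaling k10 by s (distribution
    untouched) raises the noise-free geometric-mean concentration in the
    window by ``target_fold`` relative to control. Used to set the default
    receptor-blockade scenario: the published effect is reported as a
    concentration fold-change, not a rate-constant ratio. When the design's
    ``sample_times`` are given, the fold is evaluated at the sampled times
    inside the window — exactly what the fold-change comparison measures —
    otherwise on a uniform grid across the window.
    """
    if sample_times is not None:
        t = np.asarray([s for s in sample_times
                        if window[0] <= s <= window[1]], dtype=float)
        if len(t) == 0:
            raise ValueError("no sample times inside the calibration window")
    else:
        t = np.linspace(window[0], window[1], 11)
    log_ctrl = np.mean(np.log(biexp_concentration(macro, t)))

    def log_fold(s: float) -> float:
        m = transform_macro(macro, dose, 1.0, s)
        return float(np.mean(np.log(biexp_concentration(m, t))) - log_ctrl
                     - math.log(target_fold))

    lo, hi = 1e-9, 1.0
    if log_fold(lo) < 0:
        raise ValueError("target fold-change unreachable by slowing elimination "
                         "under this disposition")
    return float(brentq(log_fold, lo, hi, xtol=1e-12, rtol=1e-12))


# --------------------------------------------------------------------------
# Organ distribution
# --------------------------------------------------------------------------

def simulate_organ_distribution(fractions_per_organ: dict,
                                organ_weights: dict,
                                dose_total: float) -> OrganDataset:
    """Construct tissue concentrations realising given %ID fractions.

    ``fractions_per_organ`` maps organ name to the fraction of the injected
    dose recovered there (0–1, summing to at most 1); tissue concentration
    is fraction * dose / organ weight, the exact inverse of the organ-uptake
    accounting.
    """
    organs = list(fractions_per_organ)
    fr = np.array([fractions_per_organ[o] for o in organs], dtype=float)
    if np.any(fr < 0):
        raise ValueError("fractions must be non-negative")
    if fr.sum() > 1.0 + 1e-12:
        raise ValueError("organ fractions sum to more than the injected dose")
    missing = [o for o in organs if o not in organ_weights]
    if missing:
        raise ValueError(f"missing organ weight(s): {missing}")
    w = np.array([organ_weights[o] for o in organs], dtype=float)
    if np.any(w <= 0):
        raise ValueError("organ weights must be positive")
    conc = fr * dose_total / w
    return OrganDataset(organs=organs, tissue_conc=conc, organ_weights=w,
                        dose_total=dose_total)
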