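"""Steady-state clearance physiology.

Partitions total elimination of an infused tracer into renal and non-renal
routes from arterial / renal-vein / urine sampling, using the standard
organ-clearance identities:

* total clearance        CL = infusion rate / arterial concentration
* renal clearance        CL_r = [Ca ERPF - Cv (ERPF - Vdot)] / Ca
* marker clearance       U Vdot / P  (inulin -> GFR, PAH -> renal plasma flow)
* extraction fraction    (Ca - Cv) / Ca

All clearances are homogeneous of degree zero in a joint rescaling of the
concentrations, so marker concentrations may be supplied in any consistent
unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .models import ClearanceReport, SteadyStateDataset

#: default upper bound on the arterial-sample CV for accepting steady state
STEADY_STATE_CV_THRESHOLD = 0.15


def total_clearance(infusion_rate: float, arterial_conc_mean: float) -> float:
    """Total plasma clearance at steady state: infusion rate / Css (mL/kg/min)."""
    if arterial_conc_mean <= 0:
        raise ValueError("arterial concentration must be positive")
    return infusion_rate / arterial_conc_mean


def renal_clearance(arterial_conc: float, renal_vein_conc: float,
                    erpf: float, urine_flow: float) -> float:
    """Renal clearance from arteriovenous extraction across the kidney.

    CL_r = [Ca * ERPF - Cv * (ERPF - Vdot)] / Ca. The renal-vein term is
    corrected for the plasma volume lost to urine. A negative result (venous
    concentration exceeding what zero extraction allows, possible under
    assay noise) is returned as-is with a warning so replicate averages
    remain unbiased.
    """
    if arterial_conc <= 0:
        raise ValueError("arterial concentration must be positive")
    if not (erpf > urine_flow >= 0):
        raise ValueError("need ERPF > urine_flow >= 0")
    cl = (arterial_conc * erpf - renal_vein_conc * (erpf - urine_flow)) / arterial_conc
    if cl < 0:
        warnings.warn("computed renal clearance is negative (venous > arterial "
                      "beyond urine-flow correction); returned unclamped",
                      RuntimeWarning, stacklevel=2)
    return cl


def marker_clearance(urine_conc: float, plasma_conc: float,
                     urine_flow: float) -> float:
    """Classical marker clearance U * Vdot / P.

    The caller labels the result: inulin clearance estimates GFR, PAH
    clearance estimates effective renal plasma flow.
    """
    if plasma_conc <= 0:
        raise ValueError("plasma marker concentration must be positive")
    return urine_conc * urine_flow / plasma_conc


def extraction_fraction(arterial_conc: float, renal_vein_conc: float) -> float:
    """Single-pass renal extraction (Ca - Cv) / Ca."""
    if arterial_conc <= 0:
        raise ValueError("arterial concentration must be positive")
    return (arterial_conc - renal_vein_conc) / arterial_conc


def renal_fraction(cl_renal: float, cl_total: float) -> float:
    """Renal share of total clearance, in percent."""
    if cl_total <= 0:
        raise ValueError("total clearance must be positive")
    return 100.0 * cl_renal / cl_total


def urinary_excretion_clearance(urine_ccn2: float, urine_flow: float,
                                arterial_conc: float) -> float:
    """Clearance attributable to intact urinary excretion: U * Vdot / Ca."""
    if arterial_conc <= 0:
        raise ValueError("arterial concentration must be positive")
    return urine_ccn2 * urine_flow / arterial_conc


def organ_uptake_fraction(tissue_conc: float, organ_weight: float,
                          dose_total: float) -> float:
    """Organ content as percent of the injected dose: 100 * C * W / dose."""
    if dose_total <= 0:
        raise ValueError("dose must be positive")
    if organ_weight < 0 or tissue_conc < 0:
        raise ValueError("tissue concentration and organ weight must be >= 0")
    return 100.0 * tissue_conc * organ_weight / dose_total


def steady_state_check(arterial_conc: Sequence[float],
                       cv_threshold: float = STEADY_STATE_CV_THRESHOLD,
                       ) -> Tuple[bool, float]:
    """Accept steady state when the arterial-sample CV is below threshold.

    Returns (passed, cv) with cv = sd/mean (ddof=1) across the samples.
    """
    conc = np.asarray(arterial_conc, dtype=float)
    if len(conc) < 2:
        raise ValueError("need >= 2 arterial samples for a steady-state check")
    mean = conc.mean()
    if mean <= 0:
        raise ValueError("arterial concentrations must be positive on average")
    cv = float(conc.std(ddof=1) / mean)
    return cv <= cv_threshold, cv


def clearance_report(ds: SteadyStateDataset,
                     cv_threshold: float = STEADY_STATE_CV_THRESHOLD,
                     ) -> ClearanceReport:
    """Full clearance partition for one steady-state dataset.

    GFR and ERPF come from the inulin and PAH marker clearances; the renal
    clearance uses the PAH-derived ERPF. A failed steady-state check is
    recorded as a flag, never a refusal.
    """
    flags = []
    passed, cv = steady_state_check(ds.arterial_conc, cv_threshold)
    if not passed:
        flags.append(f"steady-state check failed (CV {cv:.3f} > {cv_threshold})")
    ca = float(np.mean(ds.arterial_conc))
    cl_total = total_clearance(ds.infusion_rate, ca)
    gfr = marker_clearance(ds.urine_inulin, ds.plasma_inulin, ds.urine_flow)
    erpf = marker_clearance(ds.urine_pah, ds.plasma_pah, ds.urine_flow)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cl_renal = renal_clearance(ca, ds.renal_vein_conc, erpf, ds.urine_flow)
    for w in caught:
        flags.append(str(w.message))
    ef = extraction_fraction(ca, ds.renal_vein_conc)
    return ClearanceReport(
        cl_total=cl_total,
        cl_renal=cl_renal,
        cl_nonrenal=cl_total - cl_renal,
        gfr=gfr,
        erpf=erpf,
        extraction_fraction=ef,
        renal_fraction_pct=renal_fraction(cl_renal, cl_total),
        urinary_excretion_cl=urinary_excretion_clearance(
            ds.urine_ccn2, ds.urine_flow, ca),
        steady_state_cv=cv,
        steady_state_pass=passed,
        flags=flags,
    )
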