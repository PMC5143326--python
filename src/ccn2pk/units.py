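"""Unit conventions and converters.

Canonical internal units throughout the package:

==============  =====================
quantity        unit
==============  =====================
time            min
concentration   pmol/mL  (numerically equal to nM)
volume          mL/kg bodyweight
clearance/flow  mL/kg/min
dose            pmol/kg bodyweight
SPR response    pg/mm^2
==============  =====================

Converters are provided for the units that appear on published axes and in
dosing protocols (pmol/g bodyweight for mouse doses, pmol/L for assay
detection limits, percent of injected dose per mL plasma for disappearance
curves). Conversions are always explicit; no function in this package
rescales its inputs silently.
"""

from __future__ import annotations

LN2 = 0.6931471805599453


def pmol_per_g_to_pmol_per_kg(dose_pmol_per_g: float) -> float:
    """Convert a bodyweight-normalised dose from pmol/g to pmol/kg."""
    return dose_pmol_per_g * 1000.0


def pmol_per_l_to_pmol_per_ml(conc_pmol_per_l: float) -> float:
    """Convert a concentration from pmol/L to the canonical pmol/mL."""
    return conc_pmol_per_l / 1000.0


def conc_to_percent_id_per_ml(conc_pmol_per_ml: float, dose_pmol_per_kg: float) -> float:
    """Express a plasma concentration as percent of injected dose per mL.

    The result is on a per-kg-bodyweight basis: 100 * C / dose, with C in
    pmol/mL and the dose in pmol/kg, i.e. the scale used for plasma
    disappearance curves normalised to the administered amount.
    """
    if dose_pmol_per_kg <= 0:
        raise ValueError("dose must be positive")
    return 100.0 * conc_pmol_per_ml / dose_pmol_per_kg


def percent_id_per_ml_to_conc(pct_id_per_ml: float, dose_pmol_per_kg: float) -> float:
    """Inverse of :func:`conc_to_percent_id_per_ml`."""
    if dose_pmol_per_kg <= 0:
        raise ValueError("dose must be positive")
    return pct_id_per_ml * dose_pmol_per_kg / 100.0
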