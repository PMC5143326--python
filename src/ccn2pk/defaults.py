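"""Default study conditions for the synthetic experiments.

The defaults reproduce the published study design: a 25 pmol/g (25 000
pmol/kg) IV bolus in mice with destructive sampling (2 animals per time
point) and a constant-CV (10 %) ELISA with a 20 pmol/L detection limit; a
54 pmol/kg/min steady-state infusion in rats with inulin/PAH marker
clearances (GFR 9.0, renal plasma flow 30 mL/kg/min) and CCN-2 clearances
of 45 (total) and 5.4 (renal) mL/kg/min; and an SPR dilution series of
0–200 nM against immobilised LRP1 with Kd 116 nM (full-length ligand) and
112 nM (C-terminal fragment).

Quantities the experiments determine only partially are fixed here once:
the distribution-phase rate constant alpha follows from the reported
initial clearance and volume (alpha = CL_init / V1 = 120/454 per min,
half-life 2.6 min); the terminal phase, which was too close to the
detection limit to quantify in vivo, is given a plausible slow component
(intercept fraction 0.10 of C(0), beta 0.04 per min); urine flow, never
reported, defaults to 0.05 mL/kg/min.
"""

from __future__ import annotations

from .models import TwoCompartmentMacro

# ---- mouse bolus study ----------------------------------------------------
MOUSE_DOSE_PMOL_PER_KG = 25_000.0          # 25 pmol/g bodyweight
MOUSE_V1_ML_PER_KG = 454.0
MOUSE_CL_INITIAL_ML_PER_KG_MIN = 120.0
MOUSE_ALPHA_PER_MIN = MOUSE_CL_INITIAL_ML_PER_KG_MIN / MOUSE_V1_ML_PER_KG
MOUSE_BETA_PER_MIN = 0.04                  # package default; see module docstring
MOUSE_TERMINAL_FRACTION = 0.10             # B / (A + B); package default
MOUSE_SAMPLE_TIMES_MIN = (2.0, 3.0, 5.0, 7.5, 10.0, 15.0, 20.0, 30.0)
ANIMALS_PER_TIME = 2

# ---- assay ----------------------------------------------------------------
ASSAY_CV = 0.10                            # ELISA proportional error
ELISA_LOD_PMOL_PER_ML = 0.02               # 20 pmol/L

# ---- rat infusion study ---------------------------------------------------
RAT_INFUSION_RATE = 54.0                   # pmol/kg/min
RAT_CL_TOTAL = 45.0                        # mL/kg/min
RAT_CL_RENAL = 5.4
RAT_ERPF = 30.0                            # PAH clearance (renal plasma flow)
RAT_GFR = 9.0                              # inulin clearance
RAT_URINE_FLOW = 0.05                      # mL/kg/min; package default
N_ARTERIAL_SAMPLES = 3

# ---- SPR ------------------------------------------------------------------
SPR_CONCENTRATIONS_NM = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0)
SPR_KD_FULL_LENGTH_NM = 116.0
SPR_KD_C_FRAGMENT_NM = 112.0
SPR_RMAX_PG_MM2 = 10.0
SPR_NOISE_SD = 0.02 * SPR_RMAX_PG_MM2      # 2 % of Rmax, additive
SPR_KA_PER_NM_MIN = 0.05                   # kinetic traces: ka, 1/(nM min);
                                           # fast enough that equilibrium is
                                           # reached within the 2 min injection
SPR_T_ASSOC_MIN = 2.0
SPR_T_DISSOC_MIN = 2.0

# ---- interventions --------------------------------------------------------
PROTAMINE_V1_SCALE = 0.12                  # HSPG blockade: 88 % volume cut
RAP_TARGET_FOLD = 5.0                      # receptor blockade effect size
RAP_WINDOW_MIN = (10.0, 15.0)


def default_mouse_macro(dose_per_kg: float = MOUSE_DOSE_PMOL_PER_KG,
                        ) -> TwoCompartmentMacro:
    """Biexponential parameter set for the default mouse bolus scenario.

    C(0) = dose / V1 with V1 = 454 mL/kg; the distribution phase carries
    90 % of C(0) and decays at alpha = 120/454 per min; the terminal phase
    carries the remaining 10 % at beta = 0.04 per min.
    """
    c0 = dose_per_kg / MOUSE_V1_ML_PER_KG
    b = MOUSE_TERMINAL_FRACTION * c0
    return TwoCompartmentMacro(A=c0 - b, B=b,
                               alpha=MOUSE_ALPHA_PER_MIN,
                               beta=MOUSE_BETA_PER_MIN)
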