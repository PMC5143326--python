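"""Domain containers for PK curves, steady-state datasets and SPR data.

All containers are plain dataclasses holding numpy arrays or scalars in the
canonical units of :mod:`ccn2pk.units`. Validation happens at construction;
downstream code may assume the invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .units import LN2


# --------------------------------------------------------------------------
# Two-compartment disposition parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoCompartmentMacro:
    """Biexponential (macro) parameters C(t) = A e^(-alpha t) + B e^(-beta t).

    A, B are intercepts in pmol/mL; alpha, beta are hybrid rate constants in
    1/min with the distribution phase first: alpha > beta > 0.
    """

    A: float
    B: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("intercepts A, B must be non-negative")
        if not (self.alpha > self.beta > 0):
            raise ValueError("rate ordering alpha > beta > 0 violated")

    @property
    def c0(self) -> float:
        return self.A + self.B


@dataclass(frozen=True)
class TwoCompartmentMicro:
    """Central-compartment (micro) parameters.

    v1 is the initial distribution volume in mL/kg; k10 the elimination rate
    constant from the central compartment, k12/k21 the inter-compartment
    transfer constants, all in 1/min.
    """

    v1: float
    k10: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        if self.v1 <= 0 or self.k10 <= 0 or self.k21 <= 0:
            raise ValueError("v1, k10, k21 must be positive")
        if self.k12 < 0:
            raise ValueError("k12 must be non-negative")


# --------------------------------------------------------------------------
# Observation containers
# --------------------------------------------------------------------------

@dataclass
class PlasmaCurve:
    """Plasma concentration-time observations for one study arm.

    One row per animal per sampling time (destructive sampling: each animal
    contributes a single observation). Concentrations below the assay limit
    of detection carry ``censored=True`` and store the LOD value.
    """

    subject: np.ndarray          # str ids
    time_min: np.ndarray         # float, min post-injection
    conc_pmol_per_ml: np.ndarray
    censored: np.ndarray         # bool
    arm: str = "control"

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject, dtype=object)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.conc_pmol_per_ml = np.asarray(self.conc_pmol_per_ml, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        n = len(self.time_min)
        if not (len(self.subject) == len(self.conc_pmol_per_ml) == len(self.censored) == n):
            raise ValueError("all PlasmaCurve columns must have equal length")
        if np.any(self.time_min < 0):
            raise ValueError("negative sampling times")

    def __len__(self) -> int:
        return len(self.time_min)

    @property
    def observed(self) -> "PlasmaCurve":
        """Non-censored subset."""
        m = ~self.censored
        return PlasmaCurve(self.subject[m], self.time_min[m],
                           self.conc_pmol_per_ml[m], self.censored[m], self.arm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject,
            "time_min": self.time_min,
            "conc_pmol_per_ml": self.conc_pmol_per_ml,
            "censored": self.censored,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, arm: str = "control") -> "PlasmaCurve":
        required = ["subject", "time_min", "conc_pmol_per_ml", "censored"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"PlasmaCurve table missing required column(s): {missing}")
        return cls(df["subject"].to_numpy(), df["time_min"].to_numpy(),
                   df["conc_pmol_per_ml"].to_numpy(),
                   df["censored"].astype(bool).to_numpy(), arm=arm)


@dataclass
class SteadyStateDataset:
    """One steady-state infusion experiment (single animal).

    Arterial tracer samples, a renal-vein sample, urine tracer concentration
    and flow, plus inulin (GFR marker) and PAH (renal plasma flow marker)
    plasma/urine concentrations. Marker concentrations may be in any
    consistent unit; only urine/plasma ratios enter the clearance formulae.
    """

    infusion_rate: float              # pmol/kg/min
    arterial_conc: np.ndarray         # pmol/mL, >= 2 samples
    renal_vein_conc: float            # pmol/mL
    urine_flow: float                 # mL/kg/min
    urine_ccn2: float                 # pmol/mL
    plasma_inulin: float
    urine_inulin: float
    plasma_pah: float
    urine_pah: float

    def __post_init__(self) -> None:
        self.arterial_conc = np.atleast_1d(np.asarray(self.arterial_conc, dtype=float))
        if len(self.arterial_conc) < 2:
            raise ValueError("need >= 2 arterial samples for a steady-state check")
        for name in ("infusion_rate", "renal_vein_conc", "urine_flow", "urine_ccn2",
                     "plasma_inulin", "urine_inulin", "plasma_pah", "urine_pah"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if np.any(self.arterial_conc < 0):
            raise ValueError("arterial concentrations must be non-negative")


@dataclass
class SPREquilibriumDataset:
    """Equilibrium (plateau) SPR responses over an analyte dilution series."""

    concentrations: np.ndarray    # nM
    responses: np.ndarray         # pg/mm^2
    ligand_label: str = "full-length"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("negative analyte concentration")

    @property
    def nonzero(self) -> "SPREquilibriumDataset":
        m = self.concentrations > 0
        return SPREquilibriumDataset(self.concentrations[m], self.responses[m],
                                     self.ligand_label)


@dataclass
class SensorgramTrace:
    """A time-resolved SPR binding trace (association then dissociation)."""

    times: np.ndarray            # min
    responses: np.ndarray        # pg/mm^2
    concentration: float         # nM analyte during association
    injection_stop: float        # min, end of association phase

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.shape != self.responses.shape:
            raise ValueError("times and responses must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted")
        if not (self.times[0] <= self.injection_stop <= self.times[-1]):
            raise ValueError("injection_stop outside the recorded time range")


@dataclass
class OrganDataset:
    """Per-organ tissue levels after a bolus dose (whole-organ accounting)."""

    organs: list
    tissue_conc: np.ndarray      # pmol/g tissue
    organ_weights: np.ndarray    # g
    dose_total: float            # pmol injected

    def __post_init__(self) -> None:
        self.tissue_conc = np.asarray(self.tissue_conc, dtype=float)
        self.organ_weights = np.asarray(self.organ_weights, dtype=float)
        if not (len(self.organs) == len(self.tissue_conc) == len(self.organ_weights)):
            raise ValueError("organ columns must have equal length")
        if self.dose_total <= 0:
            raise ValueError("dose_total must be positive")


# --------------------------------------------------------------------------
# Result containers
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Two-compartment fit with derived PK parameters.

    Derived quantities follow the standard compartmental identities:
    v1 = dose/(A+B), auc = A/alpha + B/beta, cl_total = dose/auc,
    cl_initial = v1*alpha (distribution-phase clearance),
    t_half_initial = ln2/alpha, t_half_terminal = ln2/beta.
    """

    macro: TwoCompartmentMacro
    micro: TwoCompartmentMicro
    dose: float
    v1: float
    cl_total: float
    cl_initial: float
    t_half_initial: float
    t_half_terminal: float
    auc: float
    stderr: dict = field(default_factory=dict)
    success: bool = True
    message: str = ""
    n_used: int = 0
    n_censored: int = 0
    monoexponential: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class ClearanceReport:
    """Steady-state clearance partition for one infusion experiment."""

    cl_total: float
    cl_renal: float
    cl_nonrenal: float
    gfr: float
    erpf: float
    extraction_fraction: float
    renal_fraction_pct: float
    urinary_excretion_cl: float
    steady_state_cv: float
    steady_state_pass: bool
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AffinityFit:
    """Steady-state 1:1 Langmuir affinity estimate."""

    kd: float                 # nM
    rmax: float               # pg/mm^2
    kd_stderr: Optional[float] = None
    rmax_stderr: Optional[float] = None
    residual_rms: float = 0.0
    success: bool = True
    message: str = ""
    ligand_label: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class KineticFit:
    """Global 1:1 kinetic fit across sensorgrams at multiple concentrations."""

    ka: float                 # 1/(nM*min)
    koff: float               # 1/min
    rmax: float
    kd: float                 # koff/ka, nM
    residual_rms: float = 0.0
    success: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return asdict(self)
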