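"""File formats: headered CSV for datasets, JSON for reports, YAML for scenarios.

Column names carry their units (``time_min``, ``conc_pmol_per_ml``,
``conc_nm``, ``response_pg_mm2``) so files are self-describing. Sensorgram
CSVs store their per-trace metadata (analyte concentration, injection stop)
in ``# key: value`` comment lines above the header. Readers raise
``ValueError`` naming the offending column on malformed input; both LF and
CRLF line endings parse identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .models import (PlasmaCurve, SensorgramTrace, SPREquilibriumDataset,
                     SteadyStateDataset, TwoCompartmentMacro)
from .simulate import BolusScenario, InfusionScenario, SPRScenario

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing required column(s): {missing}")


# ---------------------------------------------------------------- plasma curves

def write_plasma_curve(curve: PlasmaCurve, path: PathLike) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_plasma_curve(path: PathLike, arm: str = "control") -> PlasmaCurve:
    df = pd.read_csv(path)
    return PlasmaCurve.from_frame(df, arm=arm)


# ------------------------------------------------------------ steady-state data

_SS_SCALARS = ["infusion_rate_pmol_per_kg_min", "renal_vein_conc_pmol_per_ml",
               "urine_flow_ml_per_kg_min", "urine_ccn2_pmol_per_ml",
               "plasma_inulin", "urine_inulin", "plasma_pah", "urine_pah"]


def write_steady_state(ds: SteadyStateDataset, path: PathLike) -> None:
    rows = [("infusion_rate_pmol_per_kg_min", ds.infusion_rate)]
    rows += [("arterial_conc_pmol_per_ml", c) for c in ds.arterial_conc]
    rows += [("renal_vein_conc_pmol_per_ml", ds.renal_vein_conc),
             ("urine_flow_ml_per_kg_min", ds.urine_flow),
             ("urine_ccn2_pmol_per_ml", ds.urine_ccn2),
             ("plasma_inulin", ds.plasma_inulin),
             ("urine_inulin", ds.urine_inulin),
             ("plasma_pah", ds.plasma_pah),
             ("urine_pah", ds.urine_pah)]
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(path, index=False)


def read_steady_state(path: PathLike) -> SteadyStateDataset:
    df = pd.read_csv(path)
    _require_columns(df, ["quantity", "value"], "steady-state")
    groups = df.groupby("quantity")["value"].apply(list).to_dict()
    missing = [q for q in _SS_SCALARS + ["arterial_conc_pmol_per_ml"]
               if q not in groups]
    if missing:
        raise ValueError(f"steady-state table missing quantity row(s): {missing}")
    return SteadyStateDataset(
        infusion_rate=groups["infusion_rate_pmol_per_kg_min"][0],
        arterial_conc=np.asarray(groups["arterial_conc_pmol_per_ml"]),
        renal_vein_conc=groups["renal_vein_conc_pmol_per_ml"][0],
        urine_flow=groups["urine_flow_ml_per_kg_min"][0],
        urine_ccn2=groups["urine_ccn2_pmol_per_ml"][0],
        plasma_inulin=groups["plasma_inulin"][0],
        urine_inulin=groups["urine_inulin"][0],
        plasma_pah=groups["plasma_pah"][0],
        urine_pah=groups["urine_pah"][0],
    )


# -------------------------------------------------------------------- SPR data

def write_spr_equilibrium(ds: SPREquilibriumDataset, path: PathLike) -> None:
    pd.DataFrame({"conc_nm": ds.concentrations,
                  "response_pg_mm2": ds.responses,
                  "ligand_label": ds.ligand_label}).to_csv(path, index=False)


def read_spr_equilibrium(path: PathLike) -> SPREquilibriumDataset:
    df = pd.read_csv(path)
    _require_columns(df, ["conc_nm", "response_pg_mm2"], "SPR equilibrium")
    label = str(df["ligand_label"].iloc[0]) if "ligand_label" in df.columns else ""
    return SPREquilibriumDataset(df["conc_nm"].to_numpy(),
                                 df["response_pg_mm2"].to_numpy(),
                                 ligand_label=label)


def write_sensorgram(trace: SensorgramTrace, path: PathLike) -> None:
    body = pd.DataFrame({"time_min": trace.times,
                         "response_pg_mm2": trace.responses}
                        ).to_csv(index=False)
    header = (f"# concentration_nm: {trace.concentration!r}\n"
              f"# injection_stop_min: {trace.injection_stop!r}\n")
    Path(path).write_text(header + body)


def read_sensorgram(path: PathLike) -> SensorgramTrace:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = float(val)
    for key in ("concentration_nm", "injection_stop_min"):
        if key not in meta:
            raise ValueError(f"sensorgram file missing '# {key}:' metadata line")
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["time_min", "response_pg_mm2"], "sensorgram")
    return SensorgramTrace(times=df["time_min"].to_numpy(),
                           responses=df["response_pg_mm2"].to_numpy(),
                           concentration=meta["concentration_nm"],
                           injection_stop=meta["injection_stop_min"])


# ------------------------------------------------------------------- scenarios

_SCENARIO_TYPES = {"bolus": BolusScenario, "infusion": InfusionScenario,
                   "spr": SPRScenario}


def write_scenario(scenario, path: PathLike) -> None:
    kind = {BolusScenario: "bolus", InfusionScenario: "infusion",
            SPRScenario: "spr"}[type(scenario)]
    d = dataclasses.asdict(scenario)
    if kind == "bolus":
        d["macro"] = dataclasses.asdict(scenario.macro)
        d["sample_times"] = list(map(float, scenario.sample_times))
    if kind == "spr":
        d["concentrations"] = list(map(float, scenario.concentrations))
    with open(path, "w") as fh:
        yaml.safe_dump({"kind": kind, **d}, fh, sort_keys=False)


def read_scenario(path: PathLike):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kind = d.pop("kind", None)
    if kind not in _SCENARIO_TYPES:
        raise ValueError(f"scenario file must declare kind in {sorted(_SCENARIO_TYPES)}")
    if kind == "bolus" and isinstance(d.get("macro"), dict):
        d["macro"] = TwoCompartmentMacro(**d["macro"])
    return _SCENARIO_TYPES[kind](**d)


# --------------------------------------------------------------------- reports

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(report, path: PathLike) -> None:
    """Serialise any result dataclass (or dict of them) as indented JSON."""
    with open(path, "w") as fh:
        json.dump(_to_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
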