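#!/usr/bin/env python
"""SPR affinity analysis: Langmuir Kd recovery and kinetic cross-check.

Simulates replicate equilibrium dilution series (0-200 nM) for the
full-length ligand (Kd 116 nM) and the C-terminal fragment (Kd 112 nM)
with additive instrument noise at 2 % of Rmax, fits the 1:1 steady-state
isotherm to each, and cross-checks the steady-state route against a global
kinetic fit of noise-free sensorgrams.

Writes results/spr_replicate_fits.csv and results/spr_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from ccn2pk import (SPRScenario, fit_kinetics, replicate_spr_fits,
                    simulate_sensorgram)
from ccn2pk.defaults import SPR_KD_C_FRAGMENT_NM

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N = 100


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fl = replicate_spr_fits(SPRScenario(), n_replicates=N, master_seed=SEED)
    fl["ligand"] = "full-length"
    cf = replicate_spr_fits(
        SPRScenario(kd=SPR_KD_C_FRAGMENT_NM, ligand_label="C-fragment"),
        n_replicates=N, master_seed=SEED)
    cf["ligand"] = "C-fragment"
    fits = pd.concat([fl, cf], ignore_index=True)
    fits.to_csv(OUT / "spr_replicate_fits.csv", index=False)

    # kinetic route on noise-free traces: Kd = koff/ka must agree
    kin_sc = SPRScenario(noise_sd=0.0, seed=SEED)
    kin = fit_kinetics([simulate_sensorgram(kin_sc, c)
                        for c in (12.5, 50.0, 200.0)])

    summary = {
        "n_replicates": N, "seed": SEED,
        "generating": {"kd_full_length_nm": 116.0,
                       "kd_c_fragment_nm": SPR_KD_C_FRAGMENT_NM},
        "median_kd_full_length_nm": float(fl["kd"].median()),
        "median_kd_c_fragment_nm": float(cf["kd"].median()),
        "kinetic_cross_check": {"ka_per_nm_min": kin.ka,
                                "koff_per_min": kin.koff,
                                "kd_nm": kin.kd},
    }
    (OUT / "spr_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"fitted {2 * N} replicate equilibrium series (seed {SEED})")
    print(f"  median Kd (full length) = {summary['median_kd_full_length_nm']:6.1f} nM "
          f"(generating 116)")
    print(f"  median Kd (C-fragment)  = {summary['median_kd_c_fragment_nm']:6.1f} nM "
          f"(generating 112)")
    print(f"  kinetic route Kd = koff/ka = {kin.kd:.1f} nM (noise-free cross-check)")
    print(f"wrote {OUT / 'spr_replicate_fits.csv'}")


if __name__ == "__main__":
    main()
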