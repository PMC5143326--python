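# ccn2pk

Disposition pharmacokinetics and receptor-binding analysis for full-length
CCN-2 (connective tissue growth factor, CTGF), a 36–38 kDa matricellular
protein whose plasma level is a candidate fibrosis biomarker. Understanding
what sets its circulating concentration requires knowing how fast and by
which routes it leaves plasma: this package implements the three
quantitative analyses of a rodent disposition study of recombinant
full-length CCN-2 — hepatic versus renal elimination, HSPG-dependent tissue
distribution, and binding to the hepatic endocytic receptor LRP1 — as a
tested, reusable pipeline over synthetic data generators that emulate each
experiment.

## The models

**Two-compartment IV bolus disposition.** The plasma curve after a bolus is
the biexponential

    C(t) = A·e^(−αt) + B·e^(−βt),   α > β > 0,

fitted by weighted nonlinear least squares (weights 1/ŷ², the
proportional-error assumption matching a constant-CV ELISA) with start
values from method-of-residuals curve stripping. Derived parameters follow
the standard identities: V1 = dose/(A+B), AUC = A/α + B/β, CL_total =
dose/AUC, initial (distribution-phase) clearance CL_init = V1·α, and
t½ = ln2/α. Censoring at the assay detection limit (20 pmol/L) is handled
by exclusion with a reported count.

**Steady-state clearance physiology.** At steady state under constant
infusion, total clearance is infusion rate / arterial concentration; renal
clearance comes from arteriovenous extraction across the kidney,

    CL_renal = [Ca·ERPF − Cv·(ERPF − V̇)] / Ca,

with the effective renal plasma flow (ERPF) and glomerular filtration rate
(GFR) measured as the PAH and inulin marker clearances U·V̇/P.

**SPR 1:1 Langmuir affinity.** Equilibrium responses over an analyte
dilution series follow R(C) = Rmax·C/(Kd + C); Kd and Rmax are fitted on
the log scale, and an independent kinetic route (global 1:1 fit of
association/dissociation sensorgrams, Kd = koff/ka) cross-checks the
steady-state estimate.

**Interventions.** Paired control/pre-treated bolus arms distinguish a
distribution effect (HSPG blockade by protamine: V1 reduced, curves shifted
in parallel) from an elimination effect (LRP1 blockade by RAP: k10 slowed,
late concentrations elevated), via the fitted V1 shift, a parallel-shift
diagnostic (CV of the treated/control concentration ratio over time), and
a windowed geometric-mean fold-change with a two-tailed t-test on
log-concentrations.

## Worked example

The numbered drivers under `analysis/` run each study end to end and write
their tables under `results/`. For example:

```sh
$ python analysis/01_mouse_bolus_pk.py
fitted 100 replicate curves (100 fits, seed 1)
  median V1      =   452.8 mL/kg (generating 454)
  median CL_init =   119.6 mL/kg/min (generating 120)
  median t1/2    =    2.60 min (generating 2.62)
```

One hundred plasma curves are simulated at the default mouse conditions
(25 000 pmol/kg bolus, two animals per time point at 2–30 min, 10 % assay
CV) from a disposition with V1 = 454 mL/kg and CL_init = 120 mL/kg/min;
each is fitted with the two-compartment model. The medians show the fitter
recovers the generating volume and clearance to within about 1 % under the
study's sparse destructive sampling. Likewise:

```sh
$ python analysis/02_rat_infusion_clearance.py
analysed 100 replicate steady-state datasets (seed 1)
  median CL_total =  45.32 mL/kg/min (generating 45)
  median CL_renal =   5.58 mL/kg/min (generating 5.4)
  median GFR      =   9.25 mL/kg/min (generating 9.0)
  median RPF      =  29.33 mL/kg/min (generating 30)
  median renal fraction = 12.6 %
```

— the renal route accounts for only ~12 % of total elimination, the
signature of predominantly hepatic clearance. `03_spr_affinity.py` recovers
Kd = 118 nM (full-length, generating 116) and 114 nM (C-fragment,
generating 112); `04_interventions.py` recovers an 88 % V1 reduction with a
near-constant concentration ratio (parallel shift) in the volume arm, and a
5-fold concentration elevation at 10–15 min with an unchanged V1 in the
elimination arm.

The same stages are scriptable from the shell: `ccn2pk simulate`,
`fit-bolus`, `clearance`, `spr-fit`, `compare` and `reproduce-study`
(see `ccn2pk --help`).

## Layout

- `src/ccn2pk/` — the library: `simulate` (scenario generators),
  `compartmental` (disposition model and fitting), `clearance`
  (steady-state physiology), `spr` (binding analysis), `pipeline`
  (study runners, replicate machinery), `io` (CSV/JSON/YAML), `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — modelling assumptions, defaults and limitations.
- `tests/` — pytest suite (unit, hypothesis property tests, acceptance).
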