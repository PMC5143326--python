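# Methods

## Disposition model

An IV bolus is modelled with the classical two-compartment mammillary
system: a central compartment of volume `v1` (mL/kg) exchanging with one
peripheral compartment (`k12`, `k21`, 1/min) and eliminating from the
central compartment (`k10`, 1/min). The plasma curve is the biexponential
`C(t) = A e^(−αt) + B e^(−βt)` with `α > β > 0`; macro (A, B, α, β) and
micro (v1, k10, k12, k21) parameterizations are interconverted by the
standard eigenvalue algebra, which satisfies `k10·k21 = αβ` and
`k10 + k12 + k21 = α + β` identically. Canonical units throughout: time in
min, concentration in pmol/mL (numerically nM for this ~37 kDa protein),
volumes in mL/kg, clearances in mL/kg/min, doses in pmol/kg; converters
are provided for pmol/g dosing and percent-of-injected-dose axes.

**"Initial clearance" is defined as V1·α**, the distribution-phase plasma
clearance. The reported triple for the mouse study — V1 = 454 mL/kg,
initial clearance 120 mL/kg/min, initial half-life 2.6 min — satisfies
`t½ = ln2·V1/CL` only under this reading (ln2·454/120 = 2.62 min), so the
package adopts it; a noncompartmental initial-slope estimate is numerically
equivalent here but is not what the derived parameter reports.

## Fitting

Fits are pooled across destructively sampled animals — one curve per study
arm, matching a design where each animal contributes a single observation —
with no inter-animal random effects. The residual is `(y − ŷ)/ŷ`
(weights 1/ŷ², the proportional-error model implied by a constant-CV
assay); `1/y²` data weighting is available as an option. All four macro
parameters are fitted on the log scale, which enforces positivity without
constraint machinery; wide log-scale bounds (±~15 natural-log units around
the data scale) keep the optimiser out of overflow territory on poorly
informative inputs. Start values come from method-of-residuals curve
stripping: the terminal phase is log-linear-regressed on the last ⌈n/3⌉
points (minimum 3, configurable), the distribution phase on the positive
early residuals. If the converged fit has α < β the phases are relabelled;
if the relative separation `(α−β)/α` falls below 1e−3 the model is treated
as unidentifiable-two-phase and a monoexponential fallback is fitted, with
the condition recorded in the result message. Observations below the
detection limit are excluded from fitting (not imputed at LOD/2) and their
count reported; exclusion is preferred because the emulated censoring rate
at the default conditions is essentially zero, so imputation machinery
would add bias risk without benefit. Standard errors are delta-method
transforms of the log-scale asymptotic errors.

## Steady-state clearance physiology

Total clearance is infusion rate over the mean arterial concentration,
accepted after a steady-state check (CV of the arterial samples below
0.15 by default; failure is a recorded flag, not a refusal). Renal
clearance uses the arteriovenous extraction formula
`[Ca·ERPF − Cv·(ERPF − V̇)]/Ca`; ERPF is taken directly as the PAH
clearance `U·V̇/P` with no hematocrit or extraction-ratio correction, and
GFR as the inulin clearance. A negative computed renal clearance (possible
when assay noise pushes the venous sample above the arterial) is returned
unclamped with a warning flag so that replicate medians remain unbiased.
The urinary excretion clearance `U_tracer·V̇/Ca` is computed alongside the
extraction-based renal clearance; the two are reported side by side rather
than merged, since they measure different things (intact excretion versus
total renal removal including tubular uptake and degradation).

## SPR analysis

Steady-state affinity fits `Req = Rmax·C/(Kd + C)` to plateau responses
(response unit pg/mm²), excluding the zero-concentration point, with Kd and
Rmax log-parameterized and initialized from a double-reciprocal regression.
The plateau is the mean of the last 10 s of the association phase by
default, with a drift (slope) diagnostic that warns when equilibrium was
not reached. Kinetic analysis globally fits the 1:1 solution
`R(t) = Req(1 − e^(−(ka·C + koff)t))` (association) and exponential decay
at `koff` (dissociation) across traces, sharing (ka, koff, Rmax); on
noise-free simulated traces the two routes agree in Kd to better than
1e−3 relative, which the test suite asserts. Binding detection calls "no
binding" when the maximum response stays below 3× a supplied instrument
noise floor, or when the isotherm fit fails or leaves Kd unconstrained
(relative standard error above 1).

## Synthetic-data generators

The generators define the study conditions; every default is either a
reported experimental value or a fixed, documented package choice.

* **Bolus curves** — dose 25 000 pmol/kg; disposition with V1 = 454 mL/kg
  and α = 120/454 per min (the reported volume and initial clearance).
  The terminal phase was not quantifiable in vivo (concentrations fell
  toward the detection limit after ~15 min), so the package fixes a
  plausible slow component: terminal intercept fraction 0.10 of C(0) and
  β = 0.04/min (terminal half-life ~17 min). Sampling at 2, 3, 5, 7.5, 10,
  15, 20 and 30 min with 2 animals per time point emulates destructive
  sparse sampling; each animal's observation carries independent mean-one
  multiplicative lognormal noise with CV 0.10 (the assay's stated
  intra/inter-assay variation), and values below 20 pmol/L are censored
  at the limit.
* **Steady-state infusion** — rate 54 pmol/kg/min with total clearance 45,
  renal clearance 5.4, GFR 9.0 and ERPF 30 mL/kg/min; urine flow, never
  reported, defaults to a physiologically plausible 0.05 mL/kg/min
  (configurable). Arterial (3 samples), renal-vein, urine and marker
  concentrations are constructed so the clearance formulae reproduce the
  scenario exactly in the noise-free limit, then perturbed independently
  with the same lognormal model; urine flow is treated as measured exactly
  (volumetric collection). The default urinary excretion clearance of
  1.0 mL/kg/min is a package choice (a small fraction of renal clearance,
  consistent with predominantly tubular uptake of filtered protein).
* **SPR** — dilution series 0, 6.25, 12.5, 25, 50, 100, 200 nM; Kd 116 nM
  (full-length) or 112 nM (C-fragment) with Rmax 10 pg/mm² and additive
  Gaussian noise at 2 % of Rmax. Kinetic traces use ka = 0.05/(nM·min)
  (hence koff = ka·Kd ≈ 5.8/min), fast enough that equilibrium is reached
  within the 2-min injection — consistent with an assay analysed at
  steady state; 2-min association and dissociation phases.
* **Interventions** — treated arms transform the control disposition in
  micro space: v1 and/or k10 scaled, k12/k21 untouched. A pure volume
  scaling leaves the curve shape fixed (parallel shift); the
  HSPG-blockade default is v1 × 0.12 (an 88 % volume reduction). The
  receptor-blockade arm slows k10 by a factor calibrated (by root-finding
  on the noise-free curves, evaluated at the design's sampling times
  inside the 10–15 min window) so the geometric-mean fold-change there is
  exactly 5; under the default disposition the calibrated factor is
  ≈ 0.082. The effect is published as a concentration fold-change, not a
  rate ratio, so the rate scaling is the package's inversion of that
  observable. Treated animals are distinct animals, so their assay errors
  are drawn independently by default (the treated seed is derived
  deterministically from the control seed); sharing the seed explicitly
  reproduces arm-identity under identity scales.
* **Organ distribution** — tissue concentrations are constructed as
  fraction × dose / organ weight, the exact inverse of the percent-injected-
  dose accounting.

All generators take explicit integer seeds (no global RNG state) and are
bit-reproducible; replicate runs derive child seeds from one master seed
via `numpy.random.SeedSequence`.

### What the generators do not emulate

Single shared parameter set per arm (no inter-animal biological
variability beyond assay noise); no proteolytic cleavage of the tracer
into fragments during the experiment; no endogenous-protein background,
assay cross-reactivity or matrix effects; no mass-transport limitation,
drift or regeneration artefacts in the SPR traces; no urine dead-space or
collection-timing error. Passing recovery tests therefore demonstrates
that the estimators are unbiased and adequately precise under the stated
noise model and design — not that they are robust to structured biological
variability absent from the generator.

## Replicate analyses and problem sizes

The recovery analyses in `analysis/` and `scripts/acceptance.py` use 100
replicate datasets per experiment family and report medians — a robust
summary under occasional hard fits — with per-replicate seeds derived from
one master seed. At these sizes the whole pipeline runs in seconds; the
sizes are the analysis design, chosen to make the median estimates stable
to a few percent.

## Known limitations

* The terminal-phase defaults (intercept fraction, β) are package choices;
  quantities dominated by the distribution phase (V1, CL_init, t½_init)
  are insensitive to them, but terminal half-life and AUC-derived total
  clearance from bolus data inherit them and should not be read as
  study-reported values.
* The renal-clearance estimator's replicate spread is intrinsically wide:
  extraction across the kidney is small (~18 %), so the estimate is a
  small difference of noisy terms scaled by ERPF. Medians over 100
  replicates are stable to roughly ±7 %.
* Pooled fitting ignores between-animal correlation structure by design
  (there is none in a destructive design) and is not suitable for rich
  per-subject sampling; no population (mixed-effects) machinery is
  provided.
* The monoexponential fallback reports a near-degenerate biexponential
  macro so downstream algebra stays total; its `k12` is conventionally 0
  and its "two-compartment" derived quantities collapse to the
  one-compartment values.
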