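"""Two-compartment IV-bolus disposition: forward model, parameter algebra,
curve-stripping initialisation, weighted nonlinear fitting and intervention
comparisons.

The disposition model is the classical biexponential

    C(t) = A e^(-alpha t) + B e^(-beta t),      alpha > beta > 0,

equivalent to a central compartment (volume v1) exchanging with a peripheral
compartment (k12, k21) and eliminating from the central compartment (k10).
Fits are weighted for proportional (constant-CV) assay error, which is the
error structure of sandwich-ELISA concentration measurements.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import lmfit
from scipy import stats

from .models import (FitResult, PlasmaCurve, TwoCompartmentMacro,
                     TwoCompartmentMicro)
from .units import LN2

#: relative alpha/beta separation below which the model is treated as
#: effectively one-compartment
DEGENERACY_TOL = 1e-3


# --------------------------------------------------------------------------
# Forward model and parameter algebra
# --------------------------------------------------------------------------

def biexp_concentration(macro: TwoCompartmentMacro, t) -> np.ndarray:
    """Evaluate C(t) = A e^(-alpha t) + B e^(-beta t) at times ``t`` (min)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    out = macro.A * np.exp(-macro.alpha * t) + macro.B * np.exp(-macro.beta * t)
    return out if out.shape else float(out)


def macro_to_micro(macro: TwoCompartmentMacro, dose: float) -> TwoCompartmentMicro:
    """Convert macro (A, B, alpha, beta) to micro (v1, k10, k12, k21) constants.

    Standard compartmental algebra:
        k21 = (A beta + B alpha)/(A + B)
        k10 = alpha beta / k21
        k12 = alpha + beta - k21 - k10
        v1  = dose / (A + B)

    The one-compartment limit B -> 0 gives k21 -> beta, k10 -> alpha and
    k12 -> 0 (clamped at 0 against roundoff).
    """
    total = macro.A + macro.B
    if total <= 0:
        raise ValueError("A + B must be positive")
    if dose <= 0:
        raise ValueError("dose must be positive")
    k21 = (macro.A * macro.beta + macro.B * macro.alpha) / total
    k10 = macro.alpha * macro.beta / k21
    k12 = max(macro.alpha + macro.beta - k21 - k10, 0.0)
    v1 = dose / total
    return TwoCompartmentMicro(v1=v1, k10=k10, k12=k12, k21=k21)


def micro_to_macro(micro: TwoCompartmentMicro, dose: float) -> TwoCompartmentMacro:
    """Convert micro constants back to the biexponential parameters.

    alpha, beta are the roots of s^2 - (k10+k12+k21) s + k10 k21 = 0; the
    intercepts follow from C(0) = dose/v1 and the eigen-decomposition.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    s = micro.k10 + micro.k12 + micro.k21
    p = micro.k10 * micro.k21
    disc = s * s - 4.0 * p
    if disc < 0:  # roundoff guard; complex roots are impossible for real rates
        disc = 0.0
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    c0 = dose / micro.v1
    if alpha == beta:
        raise ValueError("degenerate alpha == beta; scenario is ill-posed")
    A = c0 * (alpha - micro.k21) / (alpha - beta)
    B = c0 * (micro.k21 - beta) / (alpha - beta)
    return TwoCompartmentMacro(A=A, B=B, alpha=alpha, beta=beta)


def _derived(macro: TwoCompartmentMacro, dose: float) -> dict:
    micro = macro_to_micro(macro, dose)
    auc = macro.A / macro.alpha + macro.B / macro.beta
    return dict(
        micro=micro,
        v1=micro.v1,
        auc=auc,
        cl_total=dose / auc,
        cl_initial=micro.v1 * macro.alpha,
        t_half_initial=LN2 / macro.alpha,
        t_half_terminal=LN2 / macro.beta,
    )


# --------------------------------------------------------------------------
# Curve stripping (initial estimates)
# --------------------------------------------------------------------------

def curve_strip_initial_estimates(curve: PlasmaCurve,
                                  terminal_fraction: float = 1.0 / 3.0,
                                  min_terminal_points: int = 3,
                                  ) -> TwoCompartmentMacro:
    """Method-of-residuals ("feathering") start values for the biexponential.

    The terminal phase (B, beta) comes from a log-linear regression on the
    last ``ceil(n * terminal_fraction)`` points (at least
    ``min_terminal_points``); the distribution phase (A, alpha) from a
    log-linear regression on the positive residuals
    observed - B e^(-beta t) over the remaining early points.

    Input order is irrelevant: points are sorted by time internally. A pure
    monoexponential input (no positive early residuals) returns a degenerate
    macro with A ~ 0 and alpha just above beta so the terminal pair carries
    the signal.
    """
    obs = curve.observed
    if len(obs) < 4:
        raise ValueError("need >= 4 non-censored points for curve stripping")
    order = np.argsort(obs.time_min, kind="stable")
    t = obs.time_min[order]
    c = obs.conc_pmol_per_ml[order]
    if np.any(c <= 0):
        raise ValueError("non-positive concentrations cannot be log-regressed")

    n = len(t)
    n_term = max(min_terminal_points, math.ceil(n * terminal_fraction))
    n_term = min(n_term, n - 1)
    t_term, c_term = t[-n_term:], c[-n_term:]
    slope, intercept = np.polyfit(t_term, np.log(c_term), 1)
    beta = max(-slope, 1e-8)
    B = math.exp(intercept)

    t_early, c_early = t[:-n_term], c[:-n_term]
    resid = c_early - B * np.exp(-beta * t_early)
    pos = resid > 0
    if pos.sum() >= 2:
        slope_a, intercept_a = np.polyfit(t_early[pos], np.log(resid[pos]), 1)
        alpha = max(-slope_a, beta * (1.0 + 10.0 * DEGENERACY_TOL))
        A = math.exp(intercept_a)
    else:
        # monoexponential-looking data: hand the whole signal to B/beta
        alpha = beta * (1.0 + 10.0 * DEGENERACY_TOL)
        A = 1e-8 * B
    if alpha <= beta:
        alpha = beta * (1.0 + 10.0 * DEGENERACY_TOL)
    return TwoCompartmentMacro(A=A, B=B, alpha=alpha, beta=beta)


# --------------------------------------------------------------------------
# Weighted nonlinear fit
# --------------------------------------------------------------------------

def _monoexp_fit(t: np.ndarray, c: np.ndarray, dose: float,
                 n_censored: int, message: str) -> FitResult:
    """Monoexponential fallback when the two phases are not separable."""
    slope, intercept = np.polyfit(t, np.log(c), 1)
    k = max(-slope, 1e-8)
    c0 = math.exp(intercept)
    # represent as a near-degenerate biexponential so downstream algebra holds
    beta = k
    alpha = k * (1.0 + 10.0 * DEGENERACY_TOL)
    macro = TwoCompartmentMacro(A=1e-12 * c0, B=c0, alpha=alpha, beta=beta)
    d = _derived(macro, dose)
    return FitResult(macro=macro, dose=dose, stderr={}, success=True,
                     message=message, n_used=len(t), n_censored=n_censored,
                     monoexponential=True, **d)


def fit_two_compartment(curve: PlasmaCurve, dose: float,
                        weighting: str = "model",
                        start: Optional[TwoCompartmentMacro] = None,
                        ) -> FitResult:
    """Fit the biexponential disposition model to a pooled plasma curve.

    Parameters
    ----------
    curve
        Observations; censored (below-LOD) points are excluded, and their
        count reported in the result.
    dose
        Administered dose in pmol/kg.
    weighting
        ``"model"`` (default) weights residuals by 1/model^2 — the
        proportional-error assumption matching constant-CV assay noise;
        ``"data"`` weights by 1/observed^2.
    start
        Optional start values; defaults to curve-stripping estimates.

    All four parameters are fitted on the log scale (positivity by
    construction); if the optimiser converges with alpha < beta the phases
    are relabelled before derived parameters are computed. Near-degenerate
    fits (relative alpha/beta separation < 1e-3) fall back to a
    monoexponential fit with a warning recorded in the result message.
    """
    obs = curve.observed
    n_censored = int(curve.censored.sum())
    if len(obs) < 5:
        raise ValueError("need >= 5 non-censored points to fit the model")
    if weighting not in ("model", "data"):
        raise ValueError("weighting must be 'model' or 'data'")
    t = obs.time_min
    c = obs.conc_pmol_per_ml
    if np.any(c <= 0):
        raise ValueError("non-positive concentrations in fit input")

    if start is None:
        try:
            start = curve_strip_initial_estimates(curve)
        except ValueError:
            cmax = float(c.max())
            start = TwoCompartmentMacro(A=0.8 * cmax, B=0.2 * cmax,
                                        alpha=1.0 / max(t.min(), 0.5),
                                        beta=0.1 / max(t.min(), 0.5))

    # generous log-scale bounds keep the optimizer out of overflow territory
    cmax = float(c.max())
    lo_c, hi_c = math.log(cmax) - 35.0, math.log(cmax) + 15.0
    t_span = float(t.max() - t.min()) if t.max() > t.min() else 1.0
    lo_k, hi_k = math.log(1e-6 / t_span), math.log(1e4 / t_span)

    def _clipped(x, lo, hi):
        return min(max(x, lo + 1e-6), hi - 1e-6)

    params = lmfit.Parameters()
    params.add("logA", value=_clipped(math.log(max(start.A, 1e-10)), lo_c, hi_c),
               min=lo_c, max=hi_c)
    params.add("logB", value=_clipped(math.log(max(start.B, 1e-10)), lo_c, hi_c),
               min=lo_c, max=hi_c)
    params.add("logalpha", value=_clipped(math.log(start.alpha), lo_k, hi_k),
               min=lo_k, max=hi_k)
    params.add("logbeta", value=_clipped(math.log(start.beta), lo_k, hi_k),
               min=lo_k, max=hi_k)

    def residual(p):
        A, B = math.exp(p["logA"].value), math.exp(p["logB"].value)
        al, be = math.exp(p["logalpha"].value), math.exp(p["logbeta"].value)
        model = A * np.exp(-al * t) + B * np.exp(-be * t)
        denom = np.maximum(model if weighting == "model" else c, 1e-12)
        return (c - model) / denom

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = lmfit.minimize(residual, params, method="leastsq",
                                nan_policy="raise")
    if not result.success:
        raise RuntimeError(f"two-compartment fit did not converge: {result.message}")

    vals = {k: math.exp(result.params[k].value) for k in
            ("logA", "logB", "logalpha", "logbeta")}
    A, B = vals["logA"], vals["logB"]
    alpha, beta = vals["logalpha"], vals["logbeta"]
    message = str(result.message)
    if alpha < beta:  # relabel phases so the ordering invariant holds
        A, B, alpha, beta = B, A, beta, alpha
        message += " [phases relabelled]"

    if (alpha - beta) / alpha < DEGENERACY_TOL:
        return _monoexp_fit(t, c, dose, n_censored,
                            "degenerate alpha~beta: monoexponential fallback")

    macro = TwoCompartmentMacro(A=A, B=B, alpha=alpha, beta=beta)
    # delta-method SEs on the natural scale: se(x) = x * se(log x)
    stderr = {}
    for key, name, value in (("logA", "A", A), ("logB", "B", B),
                             ("logalpha", "alpha", alpha), ("logbeta", "beta", beta)):
        se = result.params[key].stderr
        stderr[name] = value * se if se is not None else None
    d = _derived(macro, dose)
    return FitResult(macro=macro, dose=dose, stderr=stderr, success=True,
                     message=message, n_used=len(obs), n_censored=n_censored,
                     **d)


# --------------------------------------------------------------------------
# Intervention comparisons
# --------------------------------------------------------------------------

def estimate_volume_shift(control: FitResult, treated: FitResult,
                          ratio_times: Optional[Sequence[float]] = None,
                          ) -> Tuple[float, float]:
    """Percent reduction in V1 between arms, with a parallel-shift diagnostic.

    Returns ``(100 * (1 - v1_treated / v1_control), ratio_cv)`` where
    ``ratio_cv`` is the coefficient of variation of the fitted
    treated/control concentration ratio over ``ratio_times`` (default: a
    grid spanning one terminal half-life of the control fit). A small CV
    means the curves are parallel on the log scale — a pure distribution
    (volume) effect; a large CV indicates an elimination-rate change.
    """
    if not (control.success and treated.success):
        raise ValueError("both fits must have converged")
    reduction = 100.0 * (1.0 - treated.v1 / control.v1)
    if ratio_times is None:
        t_max = LN2 / control.macro.beta
        ratio_times = np.linspace(0.0, t_max, 25)
    ratio_times = np.asarray(ratio_times, dtype=float)
    ratio = (biexp_concentration(treated.macro, ratio_times)
             / biexp_concentration(control.macro, ratio_times))
    ratio_cv = float(np.std(ratio, ddof=0) / np.mean(ratio))
    return reduction, ratio_cv


def fold_change(control: PlasmaCurve, treated: PlasmaCurve,
                window: Tuple[float, float]) -> dict:
    """Treated/control geometric-mean concentration ratio within a time window.

    Returns the ratio plus an equal-variance two-tailed Student t-test on the
    log-concentrations inside the window (the standard comparison for
    proportional-error assay data).
    """
    t_lo, t_hi = window
    if t_hi <= t_lo:
        raise ValueError("window must satisfy t_lo < t_hi")

    def _in_window(curve: PlasmaCurve) -> np.ndarray:
        obs = curve.observed
        m = (obs.time_min >= t_lo) & (obs.time_min <= t_hi)
        vals = obs.conc_pmol_per_ml[m]
        if len(vals) == 0:
            raise ValueError(f"{curve.arm}: no observations in window [{t_lo}, {t_hi}]")
        if np.any(vals <= 0):
            raise ValueError("non-positive concentrations in window")
        return vals

    c_ctrl = _in_window(control)
    c_trt = _in_window(treated)
    log_ctrl, log_trt = np.log(c_ctrl), np.log(c_trt)
    ratio = math.exp(float(np.mean(log_trt) - np.mean(log_ctrl)))
    if len(c_ctrl) > 1 and len(c_trt) > 1:
        tt = stats.ttest_ind(log_trt, log_ctrl, equal_var=True)
        t_stat, p_value = float(tt.statistic), float(tt.pvalue)
    else:
        t_stat, p_value = float("nan"), float("nan")
    return {"ratio": ratio, "t_statistic": t_stat, "p_value": p_value,
            "n_control": int(len(c_ctrl)), "n_treated": int(len(c_trt)),
            "window": [t_lo, t_hi]}
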