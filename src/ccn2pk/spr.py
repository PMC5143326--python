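"""Surface plasmon resonance analysis.

Steady-state affinity estimation fits the 1:1 Langmuir binding isotherm

    Req(C) = Rmax * C / (Kd + C)

to plateau responses over an analyte dilution series, with Kd and Rmax
parameterised on the log scale (positivity by construction) and start
values from a double-reciprocal linearisation. Kinetic analysis globally
fits the 1:1 association/dissociation solution across sensorgrams at
multiple concentrations, giving an independent Kd = koff/ka to
cross-check the steady-state estimate.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import lmfit

from .models import AffinityFit, KineticFit, SensorgramTrace, SPREquilibriumDataset

#: fraction of the association phase averaged for the plateau response
DEFAULT_PLATEAU_WINDOW_MIN = 10.0 / 60.0


def reference_subtract(signal: SensorgramTrace,
                       control: SensorgramTrace) -> SensorgramTrace:
    """Subtract a blank-channel trace from a signal trace, pointwise.

    The control is linearly interpolated onto the signal time grid when the
    grids differ; the control must cover the signal's time range.
    """
    if control.times[0] > signal.times[0] or control.times[-1] < signal.times[-1]:
        raise ValueError("control trace does not cover the signal time range")
    ctrl = np.interp(signal.times, control.times, control.responses)
    return SensorgramTrace(times=signal.times.copy(),
                           responses=signal.responses - ctrl,
                           concentration=signal.concentration,
                           injection_stop=signal.injection_stop)


def equilibrium_response(trace: SensorgramTrace,
                         plateau_window: float = DEFAULT_PLATEAU_WINDOW_MIN,
                         slope_warn_fraction: float = 0.01) -> float:
    """Plateau response: mean over the final window of the association phase.

    ``plateau_window`` is in the trace's time unit (minutes by convention).
    Warns when the response is still drifting across the window by more
    than ``slope_warn_fraction`` of its mean (equilibrium not reached).
    """
    if plateau_window <= 0:
        raise ValueError("plateau window must be positive")
    t0 = trace.injection_stop - plateau_window
    if t0 < trace.times[0]:
        raise ValueError("plateau window longer than the association phase")
    m = (trace.times >= t0) & (trace.times <= trace.injection_stop)
    if not np.any(m):
        raise ValueError("no samples inside the plateau window")
    resp = trace.responses[m]
    mean = float(resp.mean())
    if len(resp) > 2 and mean != 0:
        slope = np.polyfit(trace.times[m], resp, 1)[0]
        if abs(slope * plateau_window) > slope_warn_fraction * abs(mean):
            warnings.warn("response still drifting across the plateau window; "
                          "equilibrium may not have been reached",
                          RuntimeWarning, stacklevel=2)
    return mean


def _double_reciprocal_start(conc: np.ndarray, resp: np.ndarray,
                             ) -> Tuple[float, float]:
    """Start values from the linearised isotherm 1/R = 1/Rmax + (Kd/Rmax)/C."""
    pos = resp > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / conc[pos], 1.0 / resp[pos], 1)
        if intercept > 0 and slope > 0:
            return slope / intercept, 1.0 / intercept
    # fallback: Kd at the median concentration, Rmax just above the top response
    return float(np.median(conc)), float(max(resp.max(), 1e-6) * 1.5)


def fit_steady_state(dataset: SPREquilibriumDataset) -> AffinityFit:
    """Fit the 1:1 Langmuir isotherm to equilibrium responses.

    The zero-concentration point is excluded from the regression (it only
    anchors the baseline). Requires >= 4 distinct non-zero concentrations.
    """
    nz = dataset.nonzero
    if len(np.unique(nz.concentrations)) < 4:
        raise ValueError("need >= 4 distinct non-zero concentrations")
    if np.all(nz.responses <= 0):
        raise ValueError("all responses non-positive; nothing to fit")
    conc, resp = nz.concentrations, nz.responses
    kd0, rmax0 = _double_reciprocal_start(conc, resp)

    params = lmfit.Parameters()
    params.add("logkd", value=math.log(kd0))
    params.add("logrmax", value=math.log(rmax0))

    def residual(p):
        kd = math.exp(p["logkd"].value)
        rmax = math.exp(p["logrmax"].value)
        return resp - rmax * conc / (kd + conc)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"steady-state affinity fit failed: {out.message}")
    kd = math.exp(out.params["logkd"].value)
    rmax = math.exp(out.params["logrmax"].value)
    kd_se = out.params["logkd"].stderr
    rmax_se = out.params["logrmax"].stderr
    return AffinityFit(
        kd=kd, rmax=rmax,
        kd_stderr=kd * kd_se if kd_se is not None else None,
        rmax_stderr=rmax * rmax_se if rmax_se is not None else None,
        residual_rms=float(np.sqrt(np.mean(residual(out.params) ** 2))),
        success=True, message=str(out.message),
        ligand_label=dataset.ligand_label,
    )


def langmuir_response(kd: float, rmax: float, conc) -> np.ndarray:
    """Model isotherm Req = Rmax C/(Kd + C)."""
    conc = np.asarray(conc, dtype=float)
    return rmax * conc / (kd + conc)


def fit_kinetics(traces: Sequence[SensorgramTrace]) -> KineticFit:
    """Global 1:1 kinetic fit across sensorgrams at >= 2 concentrations.

    Shares (ka, koff, Rmax) across traces; association follows
    R(t) = Req (1 - e^(-(ka C + koff) t)), dissociation decays at koff from
    the response at injection stop. Returns Kd = koff/ka.
    """
    concs = {t.concentration for t in traces if t.concentration > 0}
    if len(concs) < 2:
        raise ValueError("need sensorgrams at >= 2 distinct positive concentrations")

    t_char = max(t.injection_stop for t in traces)
    r_char = max(float(np.max(np.abs(t.responses))) for t in traces)
    c_char = max(concs)

    params = lmfit.Parameters()
    params.add("logka", value=math.log(1.0 / (c_char * t_char)))
    params.add("logkoff", value=math.log(1.0 / t_char))
    params.add("logrmax", value=math.log(max(r_char, 1e-9) * 2.0))

    def residual(p):
        ka = math.exp(p["logka"].value)
        koff = math.exp(p["logkoff"].value)
        rmax = math.exp(p["logrmax"].value)
        kd = koff / ka
        res = []
        for tr in traces:
            c = tr.concentration
            req = rmax * c / (kd + c) if c > 0 else 0.0
            kobs = ka * c + koff
            model = np.empty_like(tr.responses)
            assoc = tr.times <= tr.injection_stop
            model[assoc] = req * (1.0 - np.exp(-kobs * tr.times[assoc]))
            r_stop = req * (1.0 - math.exp(-kobs * tr.injection_stop))
            model[~assoc] = r_stop * np.exp(-koff * (tr.times[~assoc] - tr.injection_stop))
            res.append(tr.responses - model)
        return np.concatenate(res)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"kinetic fit failed: {out.message}")
    ka = math.exp(out.params["logka"].value)
    koff = math.exp(out.params["logkoff"].value)
    rmax = math.exp(out.params["logrmax"].value)
    return KineticFit(ka=ka, koff=koff, rmax=rmax, kd=koff / ka,
                      residual_rms=float(np.sqrt(np.mean(residual(out.params) ** 2))),
                      success=True, message=str(out.message))


def detect_binding(dataset: SPREquilibriumDataset, noise_floor: float,
                   threshold: float = 3.0) -> bool:
    """Decide whether the dilution series shows specific binding.

    Returns False (no binding) when the largest response stays below
    ``threshold * noise_floor`` — the instrument noise level — or when the
    isotherm fit fails or leaves Kd unconstrained (relative standard error
    above 1). Otherwise True.
    """
    if noise_floor <= 0:
        raise ValueError("noise_floor must be positive")
    if float(np.max(np.abs(dataset.responses))) < threshold * noise_floor:
        return False
    try:
        fit = fit_steady_state(dataset)
    except (ValueError, RuntimeError):
        return False
    if fit.kd_stderr is None or fit.kd_stderr > fit.kd:
        return False
    return True


def inhibition_fraction(response_with_inhibitor: float,
                        response_without: float) -> float:
    """Fractional inhibition 1 - (with/without); negative values mean
    enhancement and are flagged with a warning."""
    if response_without <= 0:
        raise ValueError("baseline response must be positive")
    frac = 1.0 - response_with_inhibitor / response_without
    if frac < 0:
        warnings.warn("negative inhibition (signal enhancement in presence of "
                      "inhibitor)", RuntimeWarning, stacklevel=2)
    return frac
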