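"""Fits for the bench assay readouts: exponential dissociation traces,
K_d from dissociation-rate modulation, and dose-response midpoints (IC50).

Rates are s^-1 internally; convert min^-1 at I/O (factor 60).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ExponentialFit",
    "RateModulationFit",
    "FitError",
    "fit_exponential",
    "kd_from_rate_modulation",
    "ic50",
    "PER_MINUTE",
]

PER_MINUTE = 1.0 / 60.0  # min^-1 expressed in s^-1


class FitError(RuntimeError):
    pass


@dataclass
class ExponentialFit:
    rate: float        # s^-1
    amplitude: float
    offset: float
    residual_rms: float

    @property
    def rate_per_minute(self) -> float:
        return self.rate * 60.0


def fit_exponential(time, signal) -> ExponentialFit:
    """Least-squares fit of ``offset + amplitude * exp(-rate * t)``.

    A constant trace returns rate 0 and amplitude 0 rather than failing.
    """
    t = np.asarray(time, float)
    y = np.asarray(signal, float)
    if len(t) < 10:
        raise ValueError("need >= 10 points per fitted segment")
    span = np.ptp(y)
    scale = max(abs(y).max(), 1.0)
    if span < 1e-12 * scale:
        return ExponentialFit(0.0, 0.0, float(y.mean()), 0.0)

    def model(t, off, amp, k):
        return off + amp * np.exp(-k * t)

    # log-linear initial rate guess from the early decay
    amp0 = y[0] - y[-1]
    k0 = max(1.0 / (t[-1] - t[0]), 1e-6)
    head = y[: max(len(y) // 3, 2)] - y[-1]
    if np.all(np.sign(head) == np.sign(amp0)) and abs(amp0) > 0:
        z = np.log(np.abs(head / amp0).clip(1e-12, None))
        sl = np.polyfit(t[: len(head)], z, 1)[0]
        if sl < 0:
            k0 = -sl
    try:
        popt, _ = curve_fit(model, t, y, p0=[y[-1], amp0, k0],
                            bounds=([-np.inf, -np.inf, 0], [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    resid = y - model(t, *popt)
    return ExponentialFit(rate=float(popt[2]), amplitude=float(popt[1]),
                          offset=float(popt[0]),
                          residual_rms=float(np.sqrt(np.mean(resid**2))))


@dataclass
class RateModulationFit:
    kd: float       # M
    k_free: float   # rate without ligand
    k_sat: float    # rate at saturating ligand
    residual_rms: float


def kd_from_rate_modulation(curve: pd.DataFrame) -> RateModulationFit:
    """K_d from the ligand dependence of an observed dissociation rate.

    Fits ``k_obs(c) = (k_free*K_d + k_sat*c) / (K_d + c)`` — the fractional-
    occupancy mixture of the free and saturated rates, so the concentration
    producing half the maximal rate change equals K_d by construction.

    ``curve`` columns: conc_M, k_obs; needs >= 4 concentrations including 0.
    """
    conc = curve["conc_M"].to_numpy(float)
    kobs = curve["k_obs"].to_numpy(float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if 0.0 not in conc:
        raise ValueError("titration must include the zero-ligand point")
    k_free0 = float(kobs[conc == 0].mean())
    k_sat0 = float(kobs[np.argmax(conc)])
    if abs(k_free0 - k_sat0) < 0.02 * max(abs(k_free0), 1e-12):
        raise FitError("no rate modulation; K_d unidentifiable")

    def model(c, kd, kf, ks):
        return (kf * kd + ks * c) / (kd + c)

    kd0 = max(np.median(conc[conc > 0]), 1e-12)
    popt, _ = curve_fit(model, conc, kobs, p0=[kd0, k_free0, k_sat0],
                        bounds=([1e-15, -np.inf, -np.inf], [1.0, np.inf, np.inf]),
                        maxfev=20000)
    resid = kobs - model(conc, *popt)
    return RateModulationFit(kd=float(popt[0]), k_free=float(popt[1]),
                             k_sat=float(popt[2]),
                             residual_rms=float(np.sqrt(np.mean(resid**2))))


def ic50(dose_response: pd.DataFrame) -> float:
    """Midpoint of a monotone-decreasing dose-response.

    Four-parameter logistic fit on log10 concentration; falls back to
    monotone interpolation when the fit degenerates.  ``dose_response``
    columns: conc_M, response.
    """
    d = dose_response.sort_values("conc_M")
    conc = d["conc_M"].to_numpy(float)
    resp = d["response"].to_numpy(float)
    top = float(resp[0])  # zero-/lowest-dose response defines the reference
    if resp[-1] >= top:
        raise ValueError("response must decrease with concentration")
    half = 0.5 * top
    if resp.min() > half:
        raise ValueError("response never falls below half its zero-dose value")

    pos = conc > 0
    logc = np.log10(conc[pos])
    y = resp[pos]

    def logistic(lc, bottom, topp, mid, hill):
        return bottom + (topp - bottom) / (1 + 10 ** (hill * (lc - mid)))

    try:
        popt, _ = curve_fit(
            logistic, logc, y,
            p0=[float(y.min()), top, float(np.median(logc)), 1.0],
            maxfev=20000)
        bottom, topp, mid, hill = popt
        # the 4PL midpoint (inflection between the fitted asymptotes)
        if hill > 0 and logc.min() - 1 <= mid <= logc.max() + 1:
            return float(10 ** mid)
    except (RuntimeError, TypeError):
        pass
    # monotone interpolation fallback (exact grid hits return the grid point)
    hits = np.where(np.isclose(resp, half))[0]
    if len(hits):
        return float(conc[hits[0]])
    order = np.argsort(resp[pos])
    return float(10 ** np.interp(half, y[order], logc[order]))
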