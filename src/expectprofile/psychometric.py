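"""Cumulative-Gaussian psychometric fits for fixed-offset 2AFC data.

The probability of a clockwise response at signed orientation offset d is

    P(CW | d) = lam + (1 - 2 lam) * Phi((d - PSE) / sigma_p)

with a symmetric lapse rate lam (fixed at 0.01 by default, optionally free
in [0, 0.1]).  (PSE, sigma_p) maximize the binomial likelihood of the
per-level clockwise counts.  The *slope* is the derivative of the fitted
curve at the PSE, (1 - 2 lam) / (sigma_p sqrt(2 pi)) - the sharpening
index; the PSE displacement is the shift index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

DEFAULT_LAPSE = 0.01
LEVELS = np.array([-9.0, -7.0, -5.0, -3.0, -1.0, 1.0, 3.0, 5.0, 7.0, 9.0])


@dataclass
class PsychometricData:
    signed_deltas: np.ndarray
    n_trials: np.ndarray
    n_cw: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.signed_deltas = np.asarray(self.signed_deltas, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_cw = np.asarray(self.n_cw, dtype=int)
        if np.any(self.n_cw < 0) or np.any(self.n_cw > self.n_trials):
            raise ValueError("counts must satisfy 0 <= n_cw <= n_trials")


@dataclass
class PsychFit:
    pse: float
    sigma_p: float
    slope: float       # d P(CW)/dd at the PSE, per degree
    lapse: float
    deviance: float
    condition: str = ""


def predicted_p_cw(signed_delta, pse: float, sigma_p: float,
                   lapse: float = DEFAULT_LAPSE):
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    phi = norm.cdf((np.asarray(signed_delta, dtype=float) - pse) / sigma_p)
    return lapse + (1.0 - 2.0 * lapse) * phi


def slope_at_pse(sigma_p: float, lapse: float = DEFAULT_LAPSE) -> float:
    return (1.0 - 2.0 * lapse) / (sigma_p * np.sqrt(2.0 * np.pi))


def _binom_nll(data: PsychometricData, pse, sigma_p, lapse):
    p = predicted_p_cw(data.signed_deltas, pse, sigma_p, lapse)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(data.n_cw * np.log(p)
                         + (data.n_trials - data.n_cw) * np.log1p(-p)))


def _saturated_nll(data: PsychometricData) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = data.n_cw / data.n_trials
        terms = np.where(data.n_cw > 0, data.n_cw * np.log(phat), 0.0)
        terms = terms + np.where(data.n_trials - data.n_cw > 0,
                                 (data.n_trials - data.n_cw) * np.log1p(-phat), 0.0)
    return -float(np.sum(terms))


def fit_cumnorm(data: PsychometricData, lapse: float | None = DEFAULT_LAPSE,
                free_lapse: bool = False) -> PsychFit:
    """Binomial MLE of (PSE, sigma_p), optionally with a free lapse.

    Raises when responses are all clockwise or all counterclockwise, where
    the parameters are unidentifiable.
    """
    used = data.n_trials > 0
    if used.sum() < 2:
        raise ValueError("need at least two levels with trials")
    total_cw = int(data.n_cw[used].sum())
    total = int(data.n_trials[used].sum())
    if total_cw == 0 or total_cw == total:
        raise ValueError("all responses identical; psychometric parameters unidentifiable")

    fixed_lapse = DEFAULT_LAPSE if lapse is None else lapse
    # moment starts: PSE near the 50% crossing, sigma from the spread
    phat = np.where(used, data.n_cw / np.maximum(data.n_trials, 1), 0.5)
    pse0 = float(np.interp(0.5, phat[used], data.signed_deltas[used]))
    sig0 = max(np.ptp(data.signed_deltas[used]) / 4.0, 0.5)

    if free_lapse:
        obj = lambda p: _binom_nll(data, p[0], p[1], p[2])
        p0 = [pse0, sig0, fixed_lapse]
        bounds = [(-50.0, 50.0), (1e-3, 100.0), (0.0, 0.1)]
    else:
        obj = lambda p: _binom_nll(data, p[0], p[1], fixed_lapse)
        p0 = [pse0, sig0]
        bounds = [(-50.0, 50.0), (1e-3, 100.0)]

    best = None
    for start in (p0, [0.0, sig0] + ([fixed_lapse] if free_lapse else []),
                  [pse0, sig0 * 3.0] + ([fixed_lapse] if free_lapse else [])):
        res = minimize(obj, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    pse, sigma_p = float(best.x[0]), float(best.x[1])
    lam = float(best.x[2]) if free_lapse else fixed_lapse
    deviance = 2.0 * (best.fun - _saturated_nll(data))
    return PsychFit(pse=pse, sigma_p=sigma_p, slope=slope_at_pse(sigma_p, lam),
                    lapse=lam, deviance=float(deviance), condition=data.condition)


def psych_deltas(fits_baseline: dict, fits_main: dict) -> dict:
    """Slope and PSE differences (main - baseline) per condition plus pooled
    indices over the two anchor conditions.

    Keys follow the '<anchor>-<group>' convention used for the mixture fits.
    PSEs are on the expectward axis (negative = attracted toward the
    expected orientation), so the pooled shift is a plain average.
    """
    deltas = {}
    for key, fm in fits_main.items():
        if key not in fits_baseline:
            raise ValueError(f"missing baseline counterpart for {key!r}")
        fb = fits_baseline[key]
        deltas[key] = {"d_slope": fm.slope - fb.slope, "d_pse": fm.pse - fb.pse}
    out = {"per_condition": deltas}
    for group in ("expected", "unexpected"):
        keys = [k for k in deltas if k.endswith(f"-{group}")]
        if keys:
            out[f"pooled_d_slope_{group}"] = float(
                np.mean([deltas[k]["d_slope"] for k in keys]))
            out[f"pooled_d_pse_{group}"] = float(
                np.mean([deltas[k]["d_pse"] for k in keys]))
    return out
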