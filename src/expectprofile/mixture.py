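"""Von Mises + uniform mixture decomposition of adjustment errors.

Continuous-report orientation errors (period 180 deg) are embedded in the
full circle by angle doubling, err_rad = err_deg * pi/90, where the mixture

    p(theta) = (1 - g) * VM(theta; mu, k) + g / (2 pi)

is fit by maximum likelihood.  VM is the von Mises density
exp(k cos(theta - mu)) / (2 pi I0(k)) with I0 the modified Bessel function
of the first kind of order 0.  Reported parameters are mapped back to
orientation space: mu in degrees (halved-angle inverse scaling) and
s.d. = sqrt(1/k) converted from circular radians to degrees; g is the
guessing probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import i0e

from .observer import DEG_TO_CIRC, kappa_to_sd_deg

KAPPA_BOUNDS = (1e-4, 500.0)
MU_START_LATTICE_DEG = np.arange(-60.0, 61.0, 20.0)
KAPPA_STARTS = (0.5, 2.0, 8.0, 32.0)


def vm_pdf(x, mu: float, kappa: float):
    """Von Mises density on the circle; k = 0 degenerates to the uniform.

    Uses the exponentially scaled Bessel function for stability at large k:
    exp(k cos(d)) / (2 pi I0(k)) = exp(k (cos(d) - 1)) / (2 pi i0e(k)).
    """
    if kappa < 0:
        raise ValueError("concentration k must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.exp(kappa * (np.cos(x - mu) - 1.0)) / (2.0 * np.pi * i0e(kappa))


def mixture_loglik(errors_rad: np.ndarray, mu: float, kappa: float,
                   g: float) -> float:
    dens = (1.0 - g) * vm_pdf(errors_rad, mu, kappa) + g / (2.0 * np.pi)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


@dataclass
class MixtureFit:
    mu_deg: float      # signed shift, orientation degrees
    kappa: float       # concentration in doubled-angle circular space
    sd_deg: float      # sqrt(1/k) mapped to orientation degrees
    g: float
    loglik: float
    n: int
    condition: str = ""


def fit_mixture(errors_deg, condition: str = "", min_n: int = 20,
                n_refine: int = 3) -> MixtureFit:
    """Maximum-likelihood mixture fit to signed errors in [-90, 90) deg.

    The likelihood is multimodal in mu, so optimization is multi-start: the
    log-likelihood is evaluated on a (mu, kappa) lattice (g profiled at a
    coarse grid), and bounded L-BFGS-B is run from the ``n_refine`` best
    lattice points.
    """
    errors = np.asarray(errors_deg, dtype=float)
    if not np.all(np.isfinite(errors)):
        raise ValueError("errors contain non-finite values")
    wrapped = (errors + 90.0) % 180.0 - 90.0
    if not np.allclose(wrapped, errors, atol=1e-9):
        raise ValueError("errors must lie in [-90, 90) degrees")
    if len(errors) < min_n:
        raise ValueError(f"need at least {min_n} trials, got {len(errors)}")
    x = errors * DEG_TO_CIRC

    def nll(p):
        mu, log_k, g = p
        return -mixture_loglik(x, mu, np.exp(log_k), g)

    # coarse lattice scan
    cands = []
    for mu0 in MU_START_LATTICE_DEG * DEG_TO_CIRC:
        for k0 in KAPPA_STARTS:
            for g0 in (0.05, 0.3):
                p0 = (mu0, np.log(k0), g0)
                cands.append((nll(p0), p0))
    cands.sort(key=lambda t: t[0])

    bounds = [(-np.pi, np.pi), (np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1])),
              (0.0, 1.0)]
    best = None
    for _, p0 in cands[:n_refine]:
        res = minimize(nll, p0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res

    # Degenerate-case rule: a von Mises with k -> 0 is itself uniform, so
    # "everything is guessing" (g = 1) and "nothing is guessing but encoding
    # carries no information" (g = 0, k = 0) have equal likelihood.  When the
    # mixture does not beat the pure-guessing model by more than the BIC
    # penalty for its two extra parameters, attribute the data to guessing.
    n = len(errors)
    ll_best = -float(best.fun)
    ll_uniform = -n * np.log(2.0 * np.pi)
    if ll_best - ll_uniform < np.log(n):
        return MixtureFit(mu_deg=0.0, kappa=0.0, sd_deg=np.inf, g=1.0,
                          loglik=ll_uniform, n=n, condition=condition)

    mu, log_k, g = best.x
    kappa = float(np.exp(log_k))
    return MixtureFit(
        mu_deg=float(mu / DEG_TO_CIRC),
        kappa=kappa,
        sd_deg=float(kappa_to_sd_deg(kappa)),
        g=float(g),
        loglik=float(-best.fun),
        n=len(errors),
        condition=condition,
    )


def condition_deltas(fits_baseline: dict, fits_main: dict) -> dict:
    """Main-minus-baseline parameter deltas per condition plus pooled shifts.

    ``fits_*`` map condition labels (e.g. 'E20-expected', 'E70-unexpected';
    baseline keys use the same suffixes) to :class:`MixtureFit`.  The pooled
    expectward shift follows the convention that displacements toward 20 deg
    are negative and toward 70 deg positive: for a pair of anchor conditions
    mean shift = (shift toward 70 - shift toward 20)/2.
    """
    deltas = {}
    for key, fm in fits_main.items():
        if key not in fits_baseline:
            raise ValueError(f"missing baseline counterpart for {key!r}")
        fb = fits_baseline[key]
        deltas[key] = {
            "d_mu": fm.mu_deg - fb.mu_deg,
            "d_sd": fm.sd_deg - fb.sd_deg,
            "d_g": fm.g - fb.g,
        }
    out = {"per_condition": deltas}
    for group in ("expected", "unexpected"):
        k20, k70 = f"E20-{group}", f"E70-{group}"
        if k20 in deltas and k70 in deltas:
            out[f"pooled_shift_{group}"] = (
                deltas[k70]["d_mu"] - deltas[k20]["d_mu"]
            ) / 2.0
            out[f"pooled_d_sd_{group}"] = (
                deltas[k70]["d_sd"] + deltas[k20]["d_sd"]
            ) / 2.0
            out[f"pooled_d_g_{group}"] = (
                deltas[k70]["d_g"] + deltas[k20]["d_g"]
            ) / 2.0
    return out
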