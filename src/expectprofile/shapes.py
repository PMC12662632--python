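"""Discrimination-sensitivity profiles and monotonic vs non-monotonic shape
adjudication.

The sensitivity profile is DS(d) = DT_baseline(d) - DT_main(d) over
cue-to-stimulus distance d in {0, 10, 20, 30, 40} deg.  Two three-parameter
shapes compete for it:

* Gaussian (monotonic):    y = y0 + 2A / (w sqrt(2 pi)) * exp(-2 (x/w)^2)
* Mexican hat (center-surround, a negative second derivative of a Gaussian):
      y = 2H / (sqrt(3 m) pi^(1/4)) * exp(-x^2 / (2 m^2)) * (1 - x^2/m^2) + y1

Model comparison uses AICc and BIC under a normal error model,
AICc = N ln(RSS/N) + 2K + 2K(K+1)/(N-K-1), BIC = N ln(RSS/N) + K ln N,
and the likelihood ratio / Bayes factor of the Mexican hat over the Gaussian,
LR = exp((AICc_G - AICc_M)/2), BF = exp((BIC_G - BIC_M)/2); values above 1
favor the Mexican hat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

PROFILE_DISTANCES = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
K_PARAMS = 3  # both shapes have three parameters


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def eval_gaussian(x, y0: float, a: float, w: float):
    """Gaussian shape; ``w`` is the single width parameter (it appears in
    both the normalizer and the exponent)."""
    if w <= 0:
        raise ValueError("width w must be positive")
    x = np.asarray(x, dtype=float)
    return y0 + 2.0 * a / (w * np.sqrt(2.0 * np.pi)) * np.exp(-2.0 * (x / w) ** 2)


def eval_mexican(x, y1: float, big_h: float, m: float):
    """Mexican-hat (Ricker) shape with zero crossings at |x| = m."""
    if m <= 0:
        raise ValueError("width m must be positive")
    x = np.asarray(x, dtype=float)
    amp = 2.0 * big_h / (np.sqrt(3.0 * m) * np.pi ** 0.25)
    return amp * np.exp(-(x ** 2) / (2.0 * m ** 2)) * (1.0 - x ** 2 / m ** 2) + y1


# ---------------------------------------------------------------------------
# Information criteria and evidence ratios
# ---------------------------------------------------------------------------

def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion under normal errors."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= k + 1:
        raise ValueError("AICc correction undefined for n <= k + 1")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def bic(rss: float, n: int, k: int) -> float:
    """Bayesian information criterion under normal errors."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    return n * np.log(rss / n) + k * np.log(n)


def lr_bf(fit_gaussian: "ShapeFit", fit_mexican: "ShapeFit") -> tuple[float, float]:
    """Evidence for the Mexican hat over the Gaussian; both > 1 favor it."""
    if fit_gaussian.n_points != fit_mexican.n_points:
        raise ValueError("fits must be on identical data (same n)")
    lr = np.exp((fit_gaussian.aicc - fit_mexican.aicc) / 2.0)
    bf = np.exp((fit_gaussian.bic - fit_mexican.bic) / 2.0)
    return float(lr), float(bf)


# ---------------------------------------------------------------------------
# Profiles and fitting
# ---------------------------------------------------------------------------

@dataclass
class SensitivityProfile:
    distances: np.ndarray
    ds: np.ndarray
    task: str
    level: str = "group"  # "participant" | "group"
    pooled: bool = True   # expected-20 / expected-70 conditions averaged


@dataclass
class ShapeFit:
    model: str            # "gaussian" | "mexican"
    params: dict
    rss: float
    n_points: int
    k_params: int
    aicc: float
    bic: float
    r2: float

    def predict(self, x):
        if self.model == "gaussian":
            return eval_gaussian(x, **self.params)
        return eval_mexican(x, **self.params)


def compute_ds(threshold_table: pd.DataFrame, task: str,
               level: str = "group", pooled: bool = True) -> SensitivityProfile:
    """DS profile from a per-participant threshold table.

    ``threshold_table`` columns: participant, task, phase, condition
    (B20/B70/E20/E70), distance, dt.  Baseline and main thresholds are
    matched per (participant, condition-anchor, distance); DS is their
    difference.  With ``pooled`` the two anchor conditions are averaged.
    With ``level='group'`` the profile is the mean over participants.
    """
    sub = threshold_table[threshold_table.task == task]
    anchors = {"B20": 20, "E20": 20, "B70": 70, "E70": 70}
    sub = sub.assign(anchor=sub.condition.map(anchors))
    sub = sub[sub.distance.isin(PROFILE_DISTANCES)]  # far anchor (d=50) has no main counterpart
    wide = sub.pivot_table(index=["participant", "anchor", "distance"],
                           columns="phase", values="dt")
    for phase, dists in (("baseline", PROFILE_DISTANCES), ("main", PROFILE_DISTANCES)):
        if phase not in wide.columns:
            raise ValueError(f"threshold table lacks the {phase} phase for task {task}")
    missing = wide[wide.baseline.isna() | wide.main.isna()]
    if len(missing):
        hole = missing.index[0]
        raise ValueError(f"missing baseline/main threshold pair at {hole}")
    ds = (wide.baseline - wide.main).rename("ds").reset_index()
    if pooled:
        ds = ds.groupby(["participant", "distance"], as_index=False).ds.mean()
    if level == "group":
        prof = ds.groupby("distance", as_index=False).ds.mean()
    else:
        prof = ds
    distances = np.sort(prof.distance.unique())
    if set(distances) != set(PROFILE_DISTANCES):
        raise ValueError(f"profile distances {distances} != expected {PROFILE_DISTANCES}")
    if level == "group":
        values = prof.set_index("distance").ds.loc[distances].to_numpy()
        return SensitivityProfile(distances, values, task, "group", pooled)
    return prof  # tidy per-participant frame; fit per participant downstream


def ds_table(threshold_table: pd.DataFrame, task: str) -> pd.DataFrame:
    """Tidy per-participant DS table (participant, task, distance, ds)."""
    prof = compute_ds(threshold_table, task, level="participant")
    prof = prof.assign(task=task)
    return prof[["participant", "task", "distance", "ds"]]


_BOUNDS = {
    # (lower, upper) per parameter; widths bounded away from 0 per the fit
    # protocol (0.1, 200]; amplitudes and offsets free-signed
    "gaussian": (np.array([-np.inf, -np.inf, 0.1]), np.array([np.inf, np.inf, 200.0])),
    "mexican": (np.array([-np.inf, -np.inf, 0.1]), np.array([np.inf, np.inf, 200.0])),
}


def _residual_fn(model, x, y):
    if model == "gaussian":
        return lambda p: eval_gaussian(x, p[0], p[1], p[2]) - y
    return lambda p: eval_mexican(x, p[0], p[1], p[2]) - y


def fit_shape(profile: SensitivityProfile, model: str,
              n_starts: int = 32, seed: int = 0) -> ShapeFit:
    """Least-squares fit of one shape via seeded multi-start optimization.

    Starts are a Latin-hypercube over (offset, amplitude, width) ranges
    scaled to the data, plus a deterministic moment-based start.  The best
    residual over all converged starts wins.
    """
    if model not in ("gaussian", "mexican"):
        raise ValueError(f"unknown model {model!r}")
    x = np.asarray(profile.distances, dtype=float)
    y = np.asarray(profile.ds, dtype=float)
    if len(x) < K_PARAMS + 1:
        raise ValueError("need at least k+1 points to fit a 3-parameter shape")
    lo, hi = _BOUNDS[model]
    span = max(np.ptp(y), 1e-6)
    fun = _residual_fn(model, x, y)

    starts = [np.array([y[-1], (y[0] - y[-1]) * 20.0, 15.0])]
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    unit = sampler.random(n_starts - 1)
    low = np.array([y.min() - span, -span * 80.0, 1.0])
    high = np.array([y.max() + span, span * 80.0, 60.0])
    starts.extend(list(qmc.scale(unit, low, high)))

    best = None
    for p0 in starts:
        p0 = np.asarray(p0, dtype=float).copy()
        p0[2] = np.clip(p0[2], lo[2] + 1e-6, hi[2] - 1e-6)  # keep width feasible
        try:
            res = least_squares(fun, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"all {len(starts)} optimizer starts failed for {model}")

    rss = float(np.sum(best.fun ** 2))
    n = len(x)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-14 else -np.inf)
    rss_ic = max(rss, 1e-300)  # guard: exact fits have zero residual
    names = ("y0", "a", "w") if model == "gaussian" else ("y1", "big_h", "m")
    return ShapeFit(
        model=model,
        params=dict(zip(names, best.x)),
        rss=rss,
        n_points=n,
        k_params=K_PARAMS,
        aicc=aicc(rss_ic, n, K_PARAMS),
        bic=bic(rss_ic, n, K_PARAMS),
        r2=r2,
    )


def compare_shapes(profile: SensitivityProfile, n_starts: int = 32,
                   seed: int = 0) -> dict:
    """Fit both shapes and report the evidence for the Mexican hat."""
    fg = fit_shape(profile, "gaussian", n_starts=n_starts, seed=seed)
    fm = fit_shape(profile, "mexican", n_starts=n_starts, seed=seed)
    lr, bf = lr_bf(fg, fm)
    return {"gaussian": fg, "mexican": fm, "lr": lr, "bf": bf,
            "favored": "mexican" if lr > 1 else "gaussian"}
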