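"""Channel-encoding models of the expectation profile.

The negated discrimination thresholds over orientation are linearly
interpolated into a population response profile on a 1-degree grid, then
modeled as the sum of a bank of Gaussian tuning channels

    f(x) = A * exp(-(x - x0)^2 / sigma^2)

with six channels (preferred orientations 20..70 deg, 10-deg spacing) for
baseline profiles and five for main-phase profiles.  Three constrained fits
adjudicate how expectation reshapes the bank:

* *sharpening* - channel centers fixed on the lattice; every channel has the
  same response energy E = A_i sigma_i sqrt(pi); free parameters are the
  per-channel widths and the shared (signed) energy;
* *shift* - all channels share one amplitude and width; free parameters are
  the per-channel centers, bounded within +-5 deg of the condition's tested
  orientation range;
* *combined* - the expected-orientation channel sharpens (free width, equal
  -energy amplitude coupling) while the unexpected channels shift (free
  centers with shared amplitude and width).

Fit quality is RMSD = sqrt(SSE / (N - K)), which penalizes parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

SIGMA_BOUNDS = (0.01, 200.0)

#: nominal channel lattices (preferred orientations, deg)
BASELINE_CENTERS = np.arange(20.0, 71.0, 10.0)           # 6 channels
MAIN_CENTERS = {
    "E20": np.arange(20.0, 61.0, 10.0),                  # 5 channels
    "E70": np.arange(30.0, 71.0, 10.0),
}

#: 1-deg profile grids: tested-orientation range widened by 5 deg each side
GRID_RANGES = {
    "B20": (15.0, 75.0), "B70": (15.0, 75.0),            # 61 points
    "E20": (15.0, 65.0), "E70": (25.0, 75.0),            # 51 points
}

#: x0 bounds for the shift model, same ranges as the grids
X0_BOUNDS = GRID_RANGES


def condition_centers(condition: str) -> np.ndarray:
    if condition.startswith("B"):
        return BASELINE_CENTERS
    return MAIN_CENTERS[condition]


def condition_orientations(condition: str) -> np.ndarray:
    """Tested first-grating orientations for a condition."""
    return condition_centers(condition)


@dataclass
class PopulationProfile:
    grid: np.ndarray      # deg, 1-deg steps
    values: np.ndarray    # negated-threshold units
    phase: str
    condition: str        # B20 | B70 | E20 | E70

    @property
    def n_points(self) -> int:
        return len(self.grid)


@dataclass
class ChannelFit:
    kind: str             # sharpening | shift | combined
    condition: str
    centers: np.ndarray   # x0 per channel
    widths: np.ndarray    # sigma per channel
    amplitudes: np.ndarray
    energy: float | None  # shared A*sigma*sqrt(pi) (sharpening / combined delta-0)
    sse: float
    rmsd: float
    r2: float

    @property
    def n_channels(self) -> int:
        return len(self.centers)

    def predict(self, x) -> np.ndarray:
        return channel_sum(x, self.amplitudes, self.centers, self.widths)


def channel_sum(x, amplitudes, centers, widths) -> np.ndarray:
    x = np.asarray(x, dtype=float)[:, None]
    a = np.asarray(amplitudes, dtype=float)[None, :]
    c = np.asarray(centers, dtype=float)[None, :]
    s = np.asarray(widths, dtype=float)[None, :]
    return (a * np.exp(-((x - c) ** 2) / s ** 2)).sum(axis=1)


def rmsd(sse: float, n: int, k: int) -> float:
    """Root mean squared deviation, sqrt(SSE/(N-K)); smaller is better."""
    if n <= k:
        raise ValueError("RMSD undefined for n <= k")
    if sse < 0:
        raise ValueError("sse must be nonnegative")
    return float(np.sqrt(sse / (n - k)))


def build_population_profile(orientations, thresholds, condition: str,
                             phase: str | None = None,
                             extension: str = "linear") -> PopulationProfile:
    """Interpolate negated thresholds into a smooth profile on the 1-deg grid.

    Interior grid values are linear interpolations of -DT between tested
    orientations; the 5-deg margins beyond the tested range are filled by
    linearly extending the terminal segment (``extension='linear'``) or by
    repeating the end value (``extension='nearest'``).
    """
    orientations = np.asarray(orientations, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if len(orientations) < 2:
        raise ValueError("need at least two orientations to interpolate")
    order = np.argsort(orientations)
    xo, yo = orientations[order], -thresholds[order]
    lo, hi = GRID_RANGES[condition]
    grid = np.arange(lo, hi + 0.5, 1.0)
    values = np.interp(grid, xo, yo)
    if extension == "linear":
        left = grid < xo[0]
        right = grid > xo[-1]
        sl = (yo[1] - yo[0]) / (xo[1] - xo[0])
        sr = (yo[-1] - yo[-2]) / (xo[-1] - xo[-2])
        values[left] = yo[0] + sl * (grid[left] - xo[0])
        values[right] = yo[-1] + sr * (grid[right] - xo[-1])
    elif extension != "nearest":
        raise ValueError(f"unknown extension {extension!r}")
    if phase is None:
        phase = "baseline" if condition.startswith("B") else "main"
    return PopulationProfile(grid=grid, values=values, phase=phase,
                             condition=condition)


# ---------------------------------------------------------------------------
# Constrained fits
# ---------------------------------------------------------------------------

def _fit_stats(values, pred, k):
    resid = pred - values
    sse = float(np.sum(resid ** 2))
    tss = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else (1.0 if sse < 1e-14 else -np.inf)
    return sse, rmsd(sse, len(values), k), r2


def _multistart(fun, starts, lo, hi):
    best = None
    for p0 in starts:
        p0 = np.clip(np.asarray(p0, dtype=float), lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(fun, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best


def _lhs_starts(n_starts, lo, hi, seed, first=None):
    starts = [] if first is None else [np.asarray(first, dtype=float)]
    if n_starts > len(starts):
        sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
        unit = sampler.random(n_starts - len(starts))
        starts.extend(list(qmc.scale(unit, lo, hi)))
    return starts


def fit_sharpening(profile: PopulationProfile, n_starts: int = 12,
                   seed: int = 0, centers: np.ndarray | None = None,
                   offset: bool = False) -> ChannelFit:
    """Equal-energy bank with fixed centers; free per-channel widths and one
    shared signed energy.

    The energy (and, with ``offset=True``, an additive constant) enters the
    prediction linearly, so it is profiled out in closed form at each width
    configuration; the optimizer searches widths only.
    A_i = E / (sigma_i sqrt(pi)) exactly, so the equal-energy constraint
    holds by construction.  The default has no offset term; the flag exists
    because the no-offset bank is weakly identified on near-flat profiles
    (widths can grow to absorb the profile's DC level).

    ``centers`` overrides the condition's nominal lattice (toy problems).
    """
    if centers is None:
        centers = condition_centers(profile.condition)
    centers = np.asarray(centers, dtype=float)
    nch = len(centers)
    x, y = profile.grid, profile.values
    lo = np.full(nch, SIGMA_BOUNDS[0])
    hi = np.full(nch, SIGMA_BOUNDS[1])

    def basis(sigmas):
        # prediction per unit energy: sum_i exp(...)/(sigma_i sqrt(pi))
        s = np.asarray(sigmas)[None, :]
        g = np.exp(-((x[:, None] - centers[None, :]) ** 2) / s ** 2)
        return (g / (s * np.sqrt(np.pi))).sum(axis=1)

    def best_linear(sigmas):
        b = basis(sigmas)
        if offset:
            design = np.column_stack([b, np.ones_like(b)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            return float(coef[0]), float(coef[1]), b
        denom = float(b @ b)
        e = float(b @ y) / denom if denom > 0 else 0.0
        return e, 0.0, b

    def fun(sigmas):
        e, c, b = best_linear(sigmas)
        return e * b + c - y

    # start at the lattice-typical width plus spread starts
    starts = _lhs_starts(n_starts, np.full(nch, 2.0), np.full(nch, 40.0),
                         seed, first=np.full(nch, 10.0))
    best = _multistart(fun, starts, lo, hi)
    sigmas = best.x
    energy, const, b = best_linear(sigmas)
    amps = energy / (sigmas * np.sqrt(np.pi))
    pred = energy * b + const
    sse, rm, r2 = _fit_stats(y, pred, k=nch + 1 + int(offset))
    return ChannelFit("sharpening", profile.condition, centers.copy(), sigmas,
                      amps, energy, sse, rm, r2)


def fit_shift(profile: PopulationProfile, n_starts: int = 12,
              seed: int = 0, centers: np.ndarray | None = None,
              x0_bounds: tuple[float, float] | None = None) -> ChannelFit:
    """Shared (A, sigma) bank with free centers bounded within the
    condition's tested-orientation range widened by 5 deg (``x0_bounds``
    overrides the bounds for toy problems)."""
    centers0 = condition_centers(profile.condition) if centers is None \
        else np.asarray(centers, dtype=float)
    nch = len(centers0)
    x, y = profile.grid, profile.values
    blo, bhi = X0_BOUNDS[profile.condition] if x0_bounds is None else x0_bounds
    # params: [sigma, x0_1..x0_n]; amplitude profiled out linearly
    lo = np.concatenate([[SIGMA_BOUNDS[0]], np.full(nch, blo)])
    hi = np.concatenate([[SIGMA_BOUNDS[1]], np.full(nch, bhi)])

    def basis(p):
        s, cs = p[0], p[1:]
        return np.exp(-((x[:, None] - cs[None, :]) ** 2) / s ** 2).sum(axis=1)

    def best_amp(p):
        b = basis(p)
        denom = float(b @ b)
        return (float(b @ y) / denom if denom > 0 else 0.0), b

    def fun(p):
        a, b = best_amp(p)
        return a * b - y

    first = np.concatenate([[10.0], centers0])
    slo = np.concatenate([[2.0], np.full(nch, blo)])
    shi = np.concatenate([[40.0], np.full(nch, bhi)])
    starts = _lhs_starts(n_starts, slo, shi, seed, first=first)
    best = _multistart(fun, starts, lo, hi)
    sigma, cs = best.x[0], np.sort(best.x[1:])
    amp, b = best_amp(best.x)
    pred = amp * b
    sse, rm, r2 = _fit_stats(y, pred, k=nch + 2)
    return ChannelFit("shift", profile.condition, cs, np.full(nch, sigma),
                      np.full(nch, amp), None, sse, rm, r2)


def fit_combined(profile_baseline: PopulationProfile,
                 profile_main: PopulationProfile, n_starts: int = 12,
                 seed: int = 0) -> ChannelFit:
    """Sharpening at the expected-orientation channel plus shift of the
    unexpected channels, jointly fit to the main-phase profile.

    Parameters: expected-channel width sigma0 and energy E0 (amplitude
    coupled as E0/(sigma0 sqrt(pi))), shared unexpected (A_u, sigma_u), and
    one free center per unexpected channel.
    """
    cond = profile_main.condition
    centers0 = condition_centers(cond)
    expected = 20.0 if cond == "E20" else 70.0
    unexp = centers0[centers0 != expected]
    x, y = profile_main.grid, profile_main.values
    blo, bhi = X0_BOUNDS[cond]
    nun = len(unexp)
    # params: [sigma0, E0, sigma_u, A_u, x0_1..x0_nun]
    lo = np.concatenate([[SIGMA_BOUNDS[0], -np.inf, SIGMA_BOUNDS[0], -np.inf],
                         np.full(nun, blo)])
    hi = np.concatenate([[SIGMA_BOUNDS[1], np.inf, SIGMA_BOUNDS[1], np.inf],
                         np.full(nun, bhi)])

    def predict(p):
        s0, e0, su, au = p[:4]
        cs = p[4:]
        a0 = e0 / (s0 * np.sqrt(np.pi))
        out = a0 * np.exp(-((x - expected) ** 2) / s0 ** 2)
        out = out + (au * np.exp(-((x[:, None] - cs[None, :]) ** 2) / su ** 2)).sum(axis=1)
        return out

    fun = lambda p: predict(p) - y
    scale = float(np.mean(np.abs(y))) or 1.0
    first = np.concatenate([[10.0, -scale * 10.0 * np.sqrt(np.pi),
                             10.0, -scale], unexp])
    slo = np.concatenate([[2.0, -scale * 60.0, 2.0, -scale * 4.0], np.full(nun, blo)])
    shi = np.concatenate([[40.0, scale * 60.0, 40.0, scale * 4.0], np.full(nun, bhi)])
    starts = _lhs_starts(n_starts, slo, shi, seed, first=first)
    best = _multistart(fun, starts, lo, hi)
    s0, e0, su, au = best.x[:4]
    cs = best.x[4:]
    centers = np.concatenate([[expected], cs])
    widths = np.concatenate([[s0], np.full(nun, su)])
    amps = np.concatenate([[e0 / (s0 * np.sqrt(np.pi))], np.full(nun, au)])
    order = np.argsort(centers)
    pred = predict(best.x)
    sse, rm, r2 = _fit_stats(y, pred, k=len(best.x))
    return ChannelFit("combined", cond, centers[order], widths[order],
                      amps[order], float(e0), sse, rm, r2)


# ---------------------------------------------------------------------------
# Baseline-to-main parameter changes
# ---------------------------------------------------------------------------

@dataclass
class ChannelChange:
    condition: str
    delta_amplitude: float        # expected-orientation channel, main - baseline
    delta_width: float
    delta_location: np.ndarray    # per unexpected channel, main - baseline
    expectward_shift: float       # mean shift toward the expected orientation


def channel_changes(fit_baseline: ChannelFit, fit_main: ChannelFit) -> ChannelChange:
    """Per-channel parameter deltas between phases, matched by nominal center.

    The baseline channel with no main-phase counterpart is dropped.  For the
    shift model the per-channel location deltas are signed in orientation
    space; ``expectward_shift`` converts them to the pooled convention
    (toward 20 deg negative, toward 70 deg positive is resolved by the
    caller via :func:`mean_shift`): here it is the mean displacement toward
    the condition's expected orientation.
    """
    if fit_baseline.condition[0] != "B" or fit_main.condition[0] != "E":
        raise ValueError("expected a baseline fit and a main fit")
    cond = fit_main.condition
    expected = 20.0 if cond == "E20" else 70.0
    nominal_main = condition_centers(cond)
    nominal_base = condition_centers(fit_baseline.condition)
    # index channels by nominal lattice position
    base_idx = {c: i for i, c in enumerate(nominal_base)}
    main_idx = {c: i for i, c in enumerate(nominal_main)}
    e_b, e_m = base_idx[expected], main_idx[expected]
    # profiles are negated thresholds, so a stronger channel response is a
    # larger |A|; the amplitude delta is reported as response-strength change
    d_amp = float(abs(fit_main.amplitudes[e_m]) - abs(fit_baseline.amplitudes[e_b]))
    d_wid = float(fit_main.widths[e_m] - fit_baseline.widths[e_b])
    unexp = [c for c in nominal_main if c != expected]
    d_loc = np.array([
        (fit_main.centers[main_idx[c]] - fit_baseline.centers[base_idx[c]])
        for c in unexp
    ])
    toward = np.sign(expected - np.asarray(unexp))  # +1 if expected above channel
    expectward = float(np.mean(d_loc * toward))
    return ChannelChange(cond, d_amp, d_wid, d_loc, expectward)


def mean_shift(shift_toward_70: float, shift_toward_20: float) -> float:
    """Pooled shift, (shift toward 70 - shift toward 20)/2, with displacements
    toward 20 deg negative and toward 70 deg positive."""
    return (shift_toward_70 - shift_toward_20) / 2.0
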