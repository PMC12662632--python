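"""Ground-truth synthetic observers for the three experiment types.

An observer is a bundle of generative parameters: per-orientation baseline
discrimination thresholds, a feature-distance profile of threshold reduction
under expectation (the discrimination-sensitivity, DS, profile), a trialwise
Weibull psychometric for the staircase-controlled 2AFC tasks, a von Mises +
uniform mixture for the continuous-report adjustment task, and a cumulative
Gaussian for the fixed-offset discrimination task.

The default DS profile is a Mexican hat (negative second derivative of a
Gaussian), so the end-to-end pipeline has a center-surround generating truth;
Gaussian and flat (null) profiles are provided for power and calibration
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .shapes import eval_gaussian, eval_mexican

TWO_AFC_GUESS = 0.5


# ---------------------------------------------------------------------------
# DS (threshold-reduction) profiles over cue-to-stimulus distance
# ---------------------------------------------------------------------------

MEXICAN_M_DEFAULT = 20.0 / np.sqrt(3.0)  # surround minimum at distance 20 deg


def mexican_hat_profile(peak_ds: float = 0.8,
                        m: float = MEXICAN_M_DEFAULT) -> Callable[[float], float]:
    """Center-surround DS profile: peak ``peak_ds`` at distance 0 and an
    inhibitory surround whose minimum falls at sqrt(3)*m (20 deg under the
    default width, the center of the observed inhibitory zone)."""
    h = peak_ds * np.sqrt(3.0 * m) * np.pi ** 0.25 / 2.0
    return lambda d: eval_mexican(d, y1=0.0, big_h=h, m=m)


def gaussian_profile(peak_ds: float = 0.8, w: float = 25.0) -> Callable[[float], float]:
    """Monotonically decaying DS profile (no inhibitory surround)."""
    amp = peak_ds * w * np.sqrt(2.0 * np.pi) / 2.0
    return lambda d: eval_gaussian(d, y0=0.0, a=amp, w=w)


def flat_profile(level: float = 0.0) -> Callable[[float], float]:
    """Null observer: expectation does nothing at any distance."""
    return lambda d: level + 0.0 * np.asarray(d, dtype=float)


# ---------------------------------------------------------------------------
# Observer specification
# ---------------------------------------------------------------------------

@dataclass
class ObserverSpec:
    """Generative parameters of one simulated participant.

    2AFC tasks (OD/SFD): proportion correct at intensity x is
    ``guess + (1 - guess - lapse) * W(x; DT, beta)`` with W a Weibull scaled
    so that performance at x = DT equals the staircase target (75% correct
    with the default guess and lapse).  The main-phase threshold at
    cue-to-stimulus distance d is ``baseline_dt - ds_profile(d)``.

    Adjustment task: signed orientation error is drawn from
    ``(1-g) VonMises(mu, sd) + g Uniform`` in doubled-angle circular space,
    wrapped back to [-90, 90) degrees.

    Fixed-offset discrimination: P(clockwise) = Phi((delta - pse) / sigma),
    attenuated by a symmetric lapse.
    """

    baseline_dt_od: float = 3.0       # deg
    baseline_dt_sfd: float = 0.12     # cycles/deg
    ds_profile: Callable[[float], float] = field(default_factory=mexican_hat_profile)
    weibull_beta: float = 3.5
    lapse: float = 0.01
    guess: float = TWO_AFC_GUESS
    target_p: float = 0.75
    # adjustment truth: {(phase, delta_group): value}; see observer_conditions
    adj_mu: dict = field(default_factory=dict)
    adj_sd: dict = field(default_factory=dict)
    adj_g: dict = field(default_factory=dict)
    # fixed-offset discrimination truth
    disc_pse: dict = field(default_factory=dict)
    disc_sigma: dict = field(default_factory=dict)
    disc_lapse: float = 0.01
    tone_report_acc: float = 0.9

    def __post_init__(self):
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")
        if self.baseline_dt_od <= 0 or self.baseline_dt_sfd <= 0:
            raise ValueError("baseline thresholds must be positive")

    def baseline_dt(self, task: str) -> float:
        return self.baseline_dt_od if task == "OD" else self.baseline_dt_sfd

    def true_dt(self, task: str, phase: str, distance: float) -> float:
        """Generative discrimination threshold for a condition.

        The SFD observer shares the OD observer's DS profile, scaled into
        spatial-frequency units by the ratio of baseline thresholds (the
        orientation-space profile is task-independent by construction).
        """
        dt = self.baseline_dt(task)
        if phase == "main":
            ds = float(self.ds_profile(distance))
            if task == "SFD":
                ds *= self.baseline_dt_sfd / self.baseline_dt_od
            dt = dt - ds
        if dt <= 0:
            raise ValueError(
                f"true threshold nonpositive ({dt:.3g}) for {task} {phase} d={distance}"
            )
        return dt


def weibull_scale(dt: float, beta: float, guess: float, lapse: float,
                  target_p: float) -> float:
    """Weibull scale alpha such that performance at intensity dt hits target_p."""
    if dt <= 0:
        raise ValueError("threshold must be positive")
    w_t = (target_p - guess) / (1.0 - guess - lapse)
    if not 0.0 < w_t < 1.0:
        raise ValueError("target proportion unreachable for these guess/lapse")
    return dt / (-np.log1p(-w_t)) ** (1.0 / beta)


def p_correct_2afc(intensity, dt: float, beta: float = 3.5, guess: float = 0.5,
                   lapse: float = 0.01, target_p: float = 0.75):
    """Trialwise proportion correct of the Weibull 2AFC observer."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be nonnegative")
    alpha = weibull_scale(dt, beta, guess, lapse, target_p)
    w = -np.expm1(-((intensity / alpha) ** beta))
    return guess + (1.0 - guess - lapse) * w


def simulate_2afc_trial(observer: ObserverSpec, task: str, phase: str,
                        distance: float, intensity: float,
                        rng: np.random.Generator) -> bool:
    """One staircase-controlled 2AFC trial; returns correctness."""
    dt = observer.true_dt(task, phase, distance)
    p = p_correct_2afc(intensity, dt, observer.weibull_beta, observer.guess,
                       observer.lapse, observer.target_p)
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# Adjustment (continuous report) task
# ---------------------------------------------------------------------------

DEG_TO_CIRC = np.pi / 90.0  # doubled-angle embedding: 180 deg period -> 2*pi


def sd_deg_to_kappa(sd_deg: float) -> float:
    """Orientation-space s.d. (deg) -> von Mises concentration, via
    sd_circ = sd_deg * pi/90 and k = 1 / sd_circ^2 (s.d. = sqrt(1/k))."""
    if sd_deg <= 0:
        raise ValueError("sd must be positive")
    return 1.0 / (sd_deg * DEG_TO_CIRC) ** 2


def kappa_to_sd_deg(kappa: float) -> float:
    return np.sqrt(1.0 / kappa) / DEG_TO_CIRC


def simulate_adjustment_errors(mu_deg: float, sd_deg: float, g: float,
                               n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw signed adjustment errors (deg, wrapped to [-90, 90))."""
    if not 0.0 <= g <= 1.0:
        raise ValueError("g must lie in [0, 1]")
    guesses = rng.random(n) < g
    out = np.empty(n)
    n_guess = int(guesses.sum())
    out[guesses] = rng.uniform(-90.0, 90.0, size=n_guess)
    n_enc = n - n_guess
    if n_enc:
        kappa = sd_deg_to_kappa(sd_deg)
        circ = rng.vonmises(mu_deg * DEG_TO_CIRC, kappa, size=n_enc)
        out[~guesses] = circ / DEG_TO_CIRC
    # wrap to [-90, 90)
    return (out + 90.0) % 180.0 - 90.0


def simulate_adjustment_trial(observer: ObserverSpec, phase: str,
                              delta_group: str, rng: np.random.Generator) -> float:
    """One adjustment trial for a (phase, expected/unexpected) condition."""
    key = (phase, delta_group)
    return float(
        simulate_adjustment_errors(
            observer.adj_mu[key], observer.adj_sd[key], observer.adj_g[key], 1, rng
        )[0]
    )


# ---------------------------------------------------------------------------
# Fixed-offset discrimination task
# ---------------------------------------------------------------------------

def p_clockwise(signed_delta, pse: float, sigma: float, lapse: float = 0.0):
    """P(respond clockwise) under the cumulative-Gaussian observer."""
    from scipy.stats import norm

    if sigma <= 0:
        raise ValueError("sigma must be positive")
    phi = norm.cdf((np.asarray(signed_delta, dtype=float) - pse) / sigma)
    return lapse + (1.0 - 2.0 * lapse) * phi


def simulate_discrimination_trial(observer: ObserverSpec, phase: str,
                                  delta_group: str, signed_delta: float,
                                  rng: np.random.Generator) -> str:
    """One fixed-offset 2AFC trial; returns 'CW' or 'CCW'."""
    key = (phase, delta_group)
    p = p_clockwise(signed_delta, observer.disc_pse[key],
                    observer.disc_sigma[key], observer.disc_lapse)
    return "CW" if rng.random() < p else "CCW"


# ---------------------------------------------------------------------------
# Population defaults: the study conditions the generator emulates
# ---------------------------------------------------------------------------

# Main-phase effects follow the generative truth of the study conditions:
# unexpected-orientation representations are attracted 0.75 deg toward the
# expected orientation, encoding precision at the expected orientation
# improves by ~1 deg of s.d.; guessing is unaffected.  Effects the data did
# not support are set to zero in the truth.
ADJ_BASE_SD = 8.0
ADJ_BASE_G = 0.05
ADJ_UNEXPECTED_SHIFT = 0.75   # deg, toward the expected orientation
ADJ_EXPECTED_SD_DROP = 0.97   # deg of s.d.

DISC_BASE_SIGMA = 3.0
DISC_SLOPE_GAIN = 0.025       # per-deg slope increase at the expected orientation
DISC_UNEXPECTED_SHIFT = 0.7   # deg of expectward PSE shift at distance 25


def default_adjustment_truth(expected_sd_drop: float = ADJ_EXPECTED_SD_DROP,
                             unexpected_shift: float = ADJ_UNEXPECTED_SHIFT):
    """(mu, sd, g) truth tables keyed by (phase, delta_group).

    ``mu`` here is the *expectward* shift magnitude (positive = toward the
    expected orientation); the per-condition signed value in orientation
    space is resolved by the experiment simulator from the condition's anchor.
    """
    mu = {("baseline", "expected"): 0.0, ("baseline", "unexpected"): 0.0,
          ("main", "expected"): 0.0, ("main", "unexpected"): unexpected_shift}
    sd = {("baseline", "expected"): ADJ_BASE_SD, ("baseline", "unexpected"): ADJ_BASE_SD,
          ("main", "expected"): ADJ_BASE_SD - expected_sd_drop,
          ("main", "unexpected"): ADJ_BASE_SD}
    g = {key: ADJ_BASE_G for key in mu}
    return mu, sd, g


def default_discrimination_truth(lapse: float = 0.01):
    """(pse, sigma) truth tables keyed by (phase, delta_group).

    PSE is on the *expectward* axis (negative = attracted toward the expected
    orientation, the reporting convention of the fixed-offset experiment).
    The main-phase expected-orientation sigma is set so the psychometric
    slope (1-2*lapse)/(sigma*sqrt(2*pi)) increases by DISC_SLOPE_GAIN.
    """
    base_slope = (1.0 - 2.0 * lapse) / (DISC_BASE_SIGMA * np.sqrt(2.0 * np.pi))
    sigma_sharp = (1.0 - 2.0 * lapse) / ((base_slope + DISC_SLOPE_GAIN) * np.sqrt(2.0 * np.pi))
    pse = {("baseline", "expected"): 0.0, ("baseline", "unexpected"): 0.0,
           ("main", "expected"): 0.0, ("main", "unexpected"): -DISC_UNEXPECTED_SHIFT}
    sigma = {("baseline", "expected"): DISC_BASE_SIGMA,
             ("baseline", "unexpected"): DISC_BASE_SIGMA,
             ("main", "expected"): sigma_sharp,
             ("main", "unexpected"): DISC_BASE_SIGMA}
    return pse, sigma


def make_observer(rng: np.random.Generator | None = None,
                  profile: str = "mexican",
                  peak_ds: float = 0.8,
                  heterogeneity: float = 0.15) -> ObserverSpec:
    """Draw one participant from the synthetic population.

    ``profile`` selects the generative DS shape: "mexican" (center-surround,
    the default truth), "gaussian" (monotonic), or "flat" (null observer).
    ``heterogeneity`` is the lognormal coefficient of variation applied to
    baseline thresholds and, for non-null profiles, the DS amplitude.
    """
    if rng is None:
        rng = np.random.default_rng()
    jitter = lambda x: float(x * rng.lognormal(0.0, heterogeneity))
    if profile == "mexican":
        ds = mexican_hat_profile(peak_ds=jitter(peak_ds))
    elif profile == "gaussian":
        ds = gaussian_profile(peak_ds=jitter(peak_ds))
    elif profile == "flat":
        ds = flat_profile(0.0)
    else:
        raise ValueError(f"unknown profile kind {profile!r}")
    adj_mu, adj_sd, adj_g = default_adjustment_truth()
    disc_pse, disc_sigma = default_discrimination_truth()
    return ObserverSpec(
        baseline_dt_od=jitter(3.0),
        baseline_dt_sfd=jitter(0.12),
        ds_profile=ds,
        adj_mu=adj_mu, adj_sd=adj_sd, adj_g=adj_g,
        disc_pse=disc_pse, disc_sigma=disc_sigma,
    )
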