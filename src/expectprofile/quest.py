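"""QUEST: Bayesian adaptive staircase for 2AFC threshold estimation.

The staircase maintains a posterior over the threshold expressed in dB-like
log units, x = 20 log10(intensity), on a fixed grid spanning +-10 units
around the prior mean at 0.02 grain.  The trialwise psychometric is a
Weibull in the intensity ratio r = 10^((x - t)/20),

    P(correct | threshold t, intensity x) =
        guess + (1 - guess - lapse) * (1 - exp(-c * r^beta))

with c chosen so that performance at x = t equals the target criterion (75%
correct by default).  Trial placement and the final estimate both use the
posterior mean of the threshold distribution (mean-placement QUEST),
transformed back to stimulus units for reporting.  The bounded grid keeps a
run of early lapses from driving the recommendation off to absurd
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observer import (ObserverSpec, flat_profile, p_correct_2afc,
                       simulate_2afc_trial)

DB = 20.0 / np.log(10.0)  # 1 natural-log unit in dB


def to_db(intensity) -> np.ndarray:
    return 20.0 * np.log10(np.asarray(intensity, dtype=float))


def from_db(x) -> np.ndarray:
    return 10.0 ** (np.asarray(x, dtype=float) / 20.0)


@dataclass
class QuestState:
    grid_db: np.ndarray                  # ordered threshold grid, dB units
    posterior: np.ndarray                # normalized over the grid
    beta: float
    guess: float
    lapse: float
    target_p: float
    history: list = field(default_factory=list)  # (intensity, correct) pairs

    @property
    def n_trials(self) -> int:
        return len(self.history)


def _weibull_const(guess: float, lapse: float, target_p: float) -> float:
    w_t = (target_p - guess) / (1.0 - guess - lapse)
    if not 0.0 < w_t < 1.0:
        raise ValueError("target proportion unreachable for these guess/lapse")
    return -np.log1p(-w_t)


def p_correct_given_threshold(intensity_db: float, threshold_db,
                              beta: float, guess: float, lapse: float,
                              target_p: float):
    """Likelihood of a correct response over candidate thresholds (dB)."""
    c = _weibull_const(guess, lapse, target_p)
    ratio = 10.0 ** ((intensity_db - np.asarray(threshold_db)) / 20.0)
    w = -np.expm1(-c * ratio ** beta)
    return guess + (1.0 - guess - lapse) * w


def quest_create(prior_mean_db: float, prior_sd_db: float,
                 grid_halfwidth: float = 10.0, grain: float = 0.02,
                 beta: float = 3.5, guess: float = 0.5, lapse: float = 0.01,
                 target_p: float = 0.75) -> QuestState:
    """Fresh staircase with a normalized Gaussian prior on the dB grid."""
    if prior_sd_db <= 0:
        raise ValueError("prior_sd must be positive")
    if grain <= 0:
        raise ValueError("grain must be positive")
    grid = prior_mean_db + np.arange(-grid_halfwidth, grid_halfwidth + grain / 2,
                                     grain)
    if len(grid) == 0:
        raise ValueError("empty intensity grid")
    post = np.exp(-0.5 * ((grid - prior_mean_db) / prior_sd_db) ** 2)
    post /= post.sum()
    return QuestState(grid_db=grid, posterior=post, beta=beta, guess=guess,
                      lapse=lapse, target_p=target_p)


def quest_update(state: QuestState, intensity: float, correct) -> QuestState:
    """Bayes update of the threshold posterior after one trial (in place)."""
    if not isinstance(correct, (bool, np.bool_)):
        raise TypeError("response must be boolean")
    if not np.isfinite(intensity) or intensity <= 0:
        raise ValueError("intensity must be finite and positive")
    p = p_correct_given_threshold(float(to_db(intensity)), state.grid_db,
                                  state.beta, state.guess, state.lapse,
                                  state.target_p)
    like = p if correct else 1.0 - p
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        raise RuntimeError("posterior collapsed to zero mass")
    state.posterior = post / total
    state.history.append((float(intensity), bool(correct)))
    return state


def quest_mean_db(state: QuestState) -> float:
    return float(np.dot(state.posterior, state.grid_db))


def quest_next_intensity(state: QuestState) -> float:
    """Posterior-mean placement, clipped to the grid range, stimulus units."""
    mean = np.clip(quest_mean_db(state), state.grid_db[0], state.grid_db[-1])
    return float(from_db(mean))


def quest_final_estimate(state: QuestState) -> float:
    """Posterior-mean threshold in stimulus units."""
    if state.n_trials < 1:
        raise ValueError("threshold estimate undefined before any trial")
    return float(from_db(quest_mean_db(state)))


def run_staircase(observer: ObserverSpec, task: str, phase: str,
                  distance: float, n_trials: int, rng: np.random.Generator,
                  prior_mean: float | None = None, prior_sd_db: float = 6.0,
                  record=None, staircase_id: str = "") -> float:
    """Run one adaptive staircase against a synthetic observer.

    ``prior_mean`` is an initial threshold guess in stimulus units; by
    default the observer's baseline threshold for the task (the guess a real
    session would carry over from practice).  The prior is weak (6 dB s.d.)
    so the 40 trials dominate the estimate.  Returns the final threshold
    estimate in stimulus units; optionally appends per-trial rows to
    ``record``.
    """
    if prior_mean is None:
        prior_mean = observer.baseline_dt(task)
    state = quest_create(float(to_db(prior_mean)), prior_sd_db,
                         beta=observer.weibull_beta, guess=observer.guess,
                         lapse=observer.lapse, target_p=observer.target_p)
    for t in range(n_trials):
        intensity = quest_next_intensity(state)
        correct = simulate_2afc_trial(observer, task, phase, distance,
                                      intensity, rng)
        quest_update(state, intensity, correct)
        if record is not None:
            record.append({"staircase_id": staircase_id, "trial_index": t,
                           "intensity": intensity, "correct": correct})
    return quest_final_estimate(state)


def staircase_criterion_percent_correct(true_dt: float = 2.0,
                                        n_staircases: int = 200,
                                        n_trials: int = 40,
                                        n_probe: int = 10_000,
                                        seed: int = 1) -> float:
    """Percent correct of a known observer probed at staircase estimates.

    Runs ``n_staircases`` independent 40-trial staircases against a Weibull
    observer with true threshold ``true_dt`` (default beta and lapse), then
    tests the observer for ``n_probe`` Bernoulli trials at each returned
    estimate.  The grand mean percent correct measures how well the
    staircase lands on the 75%-correct criterion; values near 75 mean the
    estimates sit at the intended threshold.
    """
    obs = ObserverSpec(baseline_dt_od=true_dt, ds_profile=flat_profile())
    master = np.random.SeedSequence(seed)
    percents = []
    for child in master.spawn(n_staircases):
        rng = np.random.default_rng(child)
        est = run_staircase(obs, "OD", "baseline", 0.0, n_trials, rng)
        p = float(p_correct_2afc(est, dt=true_dt, beta=obs.weibull_beta,
                                 guess=obs.guess, lapse=obs.lapse,
                                 target_p=obs.target_p))
        percents.append(rng.binomial(n_probe, p) / n_probe)
    return 100.0 * float(np.mean(percents))
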