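"""Simulated experiments at study scale.

Profile experiment (per participant, per task OD/SFD):
  baseline - 2 staircases per (anchor condition in {B20, B70}, orientation in
  20..70 by 10), 40 trials each; main - per anchor condition (E20, E70),
  24 staircases at the expected orientation and 2 per unexpected orientation.
  The 24:2 staircase ratio reproduces the 75% / 6.25% trial mix of the cue
  validity structure exactly.

Adjustment experiment: 8 blocks x 48 trials baseline, 16 x 48 main, first
grating drawn from {20, 40, 50, 70} deg (expected vs unexpected groups).

Fixed-offset discrimination: 10 x 120 baseline, 20 x 160 main trials at
signed offsets +-{1,3,5,7,9} deg, first grating in {20, 45, 70} deg.

A *fast mode* replaces staircase simulation with Gaussian noise around the
generative threshold (variance calibrated to the replicate spread of the
adaptive staircases); it exists for large calibration studies (for example
false-positive rates over thousands of null cohorts) where trial-level
simulation is statistically unnecessary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .observer import (ObserverSpec, make_observer, simulate_adjustment_errors,
                       p_clockwise)
from .psychometric import LEVELS, PsychometricData
from .quest import run_staircase

PROFILE_ORIENTS = np.arange(20.0, 71.0, 10.0)
ANCHORS = {"20": 20.0, "70": 70.0}

#: empirical SD of a single 40-trial staircase estimate, as a fraction of the
#: true threshold (measured once from replicate staircases; see methods note)
STAIRCASE_CV = 0.12


def _condition_rows(anchor: float, phase: str):
    """(condition label, orientation, n staircases) rows for one anchor."""
    label = ("B" if phase == "baseline" else "E") + f"{int(anchor)}"
    rows = []
    for orient in PROFILE_ORIENTS:
        if phase == "baseline":
            n_stair = 2
        else:
            n_stair = 24 if orient == anchor else 2
            if abs(orient - anchor) > 40:
                continue  # the far anchor is never shown under this cue
        rows.append((label, orient, n_stair))
    return rows


def simulate_profile_experiment(observer: ObserverSpec, task: str,
                                participant: str, rng: np.random.Generator,
                                n_trials: int = 40,
                                fast: bool = False) -> pd.DataFrame:
    """Threshold table for one participant and task.

    Columns: participant, task, phase, condition, orientation, distance,
    dt (mean over staircases), n_staircases.
    """
    rows = []
    for phase in ("baseline", "main"):
        for anchor in (20.0, 70.0):
            for cond, orient, n_stair in _condition_rows(anchor, phase):
                distance = abs(orient - anchor)
                true_dt = observer.true_dt(task, phase, distance)
                if fast:
                    ests = true_dt * (
                        1.0 + STAIRCASE_CV * rng.standard_normal(n_stair)
                    )
                    ests = np.maximum(ests, 1e-6)
                else:
                    ests = [run_staircase(observer, task, phase, distance,
                                          n_trials, rng)
                            for _ in range(n_stair)]
                rows.append({
                    "participant": participant, "task": task, "phase": phase,
                    "condition": cond, "orientation": orient,
                    "distance": distance, "dt": float(np.mean(ests)),
                    "n_staircases": n_stair,
                })
    return pd.DataFrame(rows)


def simulate_profile_cohort(n_participants: int = 24, tasks=("OD", "SFD"),
                            profile: str = "mexican", seed: int = 0,
                            fast: bool = False, n_trials: int = 40) -> pd.DataFrame:
    """Threshold tables for a cohort; one master seed per participant."""
    master = np.random.SeedSequence(seed)
    tables = []
    for i, child in enumerate(master.spawn(n_participants)):
        rng = np.random.default_rng(child)
        obs = make_observer(rng, profile=profile)
        for task in tasks:
            tables.append(simulate_profile_experiment(
                obs, task, f"P{i:02d}", rng, n_trials=n_trials, fast=fast))
    return pd.concat(tables, ignore_index=True)


TRIAL_COLUMNS = ["participant_id", "phase", "task", "cue_tone",
                 "expected_orientation", "first_orientation", "distance",
                 "stimulus_delta", "response", "correct", "adjust_error",
                 "staircase_id", "trial_index", "tone_report_correct"]


def simulate_profile_trials(observer: ObserverSpec, task: str,
                            participant: str, rng: np.random.Generator,
                            n_trials: int = 40,
                            tone_map: dict | None = None) -> pd.DataFrame:
    """Trial-level records for the profile experiment (one participant/task).

    Each staircase trial is logged with its cue tone, gratings, signed
    stimulus difference, 2AFC response code, correctness, and the secondary
    tone-report correctness (Bernoulli at the observer's configured
    accuracy, identical across conditions by construction).
    """
    if tone_map is None:
        tone_map = {20.0: "low", 70.0: "high"}
    rows = []
    for phase in ("baseline", "main"):
        for anchor in (20.0, 70.0):
            for cond, orient, n_stair in _condition_rows(anchor, phase):
                distance = abs(orient - anchor)
                for s in range(n_stair):
                    sid = f"{participant}-{task}-{cond}-{int(orient)}-{s}"
                    rec = []
                    run_staircase(observer, task, phase, distance, n_trials,
                                  rng, record=rec, staircase_id=sid)
                    for r in rec:
                        sign = 1.0 if rng.random() < 0.5 else -1.0
                        correct = r["correct"]
                        if task == "OD":
                            resp = ("CW" if sign > 0 else "CCW") if correct \
                                else ("CCW" if sign > 0 else "CW")
                        else:
                            resp = ("higher" if sign > 0 else "lower") if correct \
                                else ("lower" if sign > 0 else "higher")
                        rows.append({
                            "participant_id": participant, "phase": phase,
                            "task": task, "cue_tone": tone_map[anchor],
                            "expected_orientation": anchor,
                            "first_orientation": orient,
                            "distance": distance,
                            "stimulus_delta": sign * r["intensity"],
                            "response": resp, "correct": correct,
                            "adjust_error": None,
                            "staircase_id": r["staircase_id"],
                            "trial_index": r["trial_index"],
                            "tone_report_correct":
                                bool(rng.random() < observer.tone_report_acc),
                        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# Adjustment experiment
# ---------------------------------------------------------------------------

def _adj_signed_mu(anchor: float, orientation: float, expectward_mu: float) -> float:
    """Signed orientation-space shift: positive = toward larger angles."""
    if orientation == anchor:
        return expectward_mu  # expected condition: truth is already 0-centred
    return expectward_mu * np.sign(anchor - orientation)


def simulate_adjustment_experiment(observer: ObserverSpec, participant: str,
                                   rng: np.random.Generator,
                                   n_baseline: int = 8 * 48,
                                   n_main: int = 16 * 48) -> pd.DataFrame:
    """Trial table: participant, phase, condition, delta_group,
    first_orientation, adjust_error (deg in [-90, 90))."""
    rows = []
    for phase, n_total in (("baseline", n_baseline), ("main", n_main)):
        for anchor in (20.0, 70.0):
            if phase == "baseline":
                orients, weights = [20.0, 40.0, 50.0, 70.0], [0.25] * 4
            else:
                # cued anchor 75%; remaining mass over the two mid gratings
                others = [o for o in (40.0, 50.0)]
                orients = [anchor] + others
                weights = [0.75] + [0.125] * 2
            n_cond = n_total // 2
            draws = rng.choice(orients, size=n_cond, p=weights)
            for orient in np.unique(draws):
                n_o = int((draws == orient).sum())
                group = "expected" if orient == anchor else "unexpected"
                key = (phase, group)
                mu = _adj_signed_mu(anchor, orient,
                                    observer.adj_mu[key]) if phase == "main" else 0.0
                errs = simulate_adjustment_errors(
                    mu, observer.adj_sd[key], observer.adj_g[key], n_o, rng)
                cond = f"E{int(anchor)}" if phase == "main" else f"B{int(anchor)}"
                for e in errs:
                    rows.append({
                        "participant": participant, "phase": phase,
                        "condition": cond, "delta_group": group,
                        "first_orientation": orient, "adjust_error": float(e),
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixed-offset discrimination experiment
# ---------------------------------------------------------------------------

def simulate_discrimination_experiment(observer: ObserverSpec, participant: str,
                                       rng: np.random.Generator,
                                       n_baseline: int = 10 * 120,
                                       n_main: int = 20 * 160) -> pd.DataFrame:
    """Per-level clockwise counts on the expectward axis.

    Columns: participant, phase, condition, delta_group, signed_delta
    (expectward axis: positive = away from the expected orientation),
    n_trials, n_cw.
    """
    rows = []
    for phase, n_total in (("baseline", n_baseline), ("main", n_main)):
        for anchor in (20.0, 70.0):
            if phase == "baseline":
                orients, weights = [anchor, 45.0], [0.5, 0.5]
            else:
                orients, weights = [anchor, 45.0], [0.75, 0.25]
            n_cond = n_total // 2
            draws = rng.choice(orients, size=n_cond, p=weights)
            for orient in np.unique(draws):
                n_o = int((draws == orient).sum())
                group = "expected" if orient == anchor else "unexpected"
                key = (phase, group)
                per_level = np.full(len(LEVELS), n_o // len(LEVELS), dtype=int)
                per_level[: n_o % len(LEVELS)] += 1
                cond = ("E" if phase == "main" else "B") + f"{int(anchor)}"
                for lvl, n_l in zip(LEVELS, per_level):
                    p = p_clockwise(lvl, observer.disc_pse[key],
                                    observer.disc_sigma[key],
                                    observer.disc_lapse)
                    n_cw = int(rng.binomial(n_l, p)) if n_l else 0
                    rows.append({
                        "participant": participant, "phase": phase,
                        "condition": cond, "delta_group": group,
                        "signed_delta": float(lvl), "n_trials": int(n_l),
                        "n_cw": n_cw,
                    })
    return pd.DataFrame(rows)


def psychometric_data_from_counts(counts: pd.DataFrame,
                                  condition: str = "") -> PsychometricData:
    agg = counts.groupby("signed_delta", as_index=False)[["n_trials", "n_cw"]].sum()
    return PsychometricData(agg.signed_delta.to_numpy(),
                            agg.n_trials.to_numpy(), agg.n_cw.to_numpy(),
                            condition=condition)
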