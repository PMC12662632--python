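"""Experimental designs for the expectation-profile paradigm.

Three experiment types share one cueing structure: an auditory tone (low or
high) precedes a grating whose orientation is drawn from a tone-conditional
distribution.  In the *baseline* phase the tone is uninformative (each listed
orientation is equally likely given either tone); in the *main* phase each
tone predicts one of two anchor orientations (20 deg or 70 deg) with a fixed
validity, the residual probability mass being split equally over the
non-predicted orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: anchor orientations predicted by the two tones in the main phase
EXPECTED_ORIENTATIONS = (20.0, 70.0)

#: orientations of the first grating in each experiment type
PROFILE_ORIENTATIONS = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
ADJUST_ORIENTATIONS = (20.0, 40.0, 50.0, 70.0)
DISC_ORIENTATIONS = (20.0, 45.0, 70.0)

#: signed offsets of the second grating in the fixed-offset discrimination task
DISC_OFFSETS = (-9.0, -7.0, -5.0, -3.0, -1.0, 1.0, 3.0, 5.0, 7.0, 9.0)

TONES = ("low", "high")


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one phase of one experiment.

    ``tone_map`` records the counterbalancing of tone onto expected
    orientation; ``validity`` is the probability that the cued orientation is
    shown given its tone in the main phase (ignored in baseline, where every
    orientation is equiprobable given either tone).
    """

    phase: str  # "baseline" | "main"
    task: str  # "OD" | "SFD" | "ADJ" | "DISC"
    orientations: tuple = PROFILE_ORIENTATIONS
    expected_orientations: tuple = EXPECTED_ORIENTATIONS
    validity: float = 0.75
    trials_per_staircase: int = 40
    staircases_expected: int = 24
    staircases_unexpected: int = 2
    staircases_baseline: int = 2
    discrimination_offsets: tuple = DISC_OFFSETS
    tone_map: dict = field(default_factory=lambda: {"low": 20.0, "high": 70.0})
    seed: int = 0

    def __post_init__(self):
        if self.phase not in ("baseline", "main"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.task not in ("OD", "SFD", "ADJ", "DISC"):
            raise ValueError(f"unknown task {self.task!r}")
        if not 0.0 <= self.validity <= 1.0:
            raise ValueError(f"validity must lie in [0, 1], got {self.validity}")
        for o in self.orientations:
            if not 0.0 <= o < 180.0:
                raise ValueError(f"orientation {o} outside [0, 180)")
        for e in self.expected_orientations:
            if e not in self.orientations:
                raise ValueError(f"expected orientation {e} not among orientations")
        if self.trials_per_staircase <= 0:
            raise ValueError("trials_per_staircase must be positive")


def design_probability_table(spec: DesignSpec) -> pd.DataFrame:
    """Exact tone-conditional orientation probabilities (not sampled).

    Returns a tidy frame with columns ``tone``, ``expected_orientation``,
    ``orientation``, ``probability``.  Probabilities sum to 1 per tone.
    """
    rows = []
    n = len(spec.orientations)
    non_predicted = [o for o in spec.orientations
                     if o not in spec.expected_orientations]
    for tone in TONES:
        cued = spec.tone_map[tone]
        for o in spec.orientations:
            if spec.phase == "baseline":
                p = 1.0 / n
            elif o == cued:
                p = spec.validity
            elif o in non_predicted:
                # residual mass split equally over the non-predicted
                # orientations; the other anchor is never shown
                p = (1.0 - spec.validity) / len(non_predicted)
            else:
                p = 0.0
            rows.append(
                {
                    "tone": tone,
                    "expected_orientation": cued,
                    "orientation": o,
                    "probability": p,
                }
            )
    return pd.DataFrame(rows)


def sample_trial_stubs(spec: DesignSpec, n_trials: int,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample a seeded, reproducible trial stream from the design table.

    Each stub carries the cue tone, the expected (cued) orientation, the
    first-grating orientation, and the absolute cue-to-stimulus distance.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    table = design_probability_table(spec)
    tones = rng.choice(TONES, size=n_trials)
    orientations = np.empty(n_trials)
    for tone in TONES:
        mask = tones == tone
        sub = table[table.tone == tone]
        orientations[mask] = rng.choice(
            sub.orientation.to_numpy(), size=int(mask.sum()), p=sub.probability.to_numpy()
        )
    expected = np.array([spec.tone_map[t] for t in tones])
    return pd.DataFrame(
        {
            "tone": tones,
            "expected_orientation": expected,
            "first_orientation": orientations,
            "distance": np.abs(orientations - expected),
        }
    )


def build_design(spec: DesignSpec, n_trials: int = 0):
    """Return the exact probability table and (optionally) sampled stubs.

    The table is exact by construction; the stub stream is sampled with the
    spec's seed so repeated calls are bit-identical.  The tone-to-orientation
    counterbalancing is whatever ``spec.tone_map`` records.
    """
    table = design_probability_table(spec)
    stubs = sample_trial_stubs(spec, n_trials) if n_trials else None
    return table, stubs


def flipped(spec: DesignSpec) -> DesignSpec:
    """Spec with the tone-to-expected-orientation mapping swapped
    (counterbalancing across participants)."""
    lo, hi = spec.tone_map["low"], spec.tone_map["high"]
    return replace(spec, tone_map={"low": hi, "high": lo})
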