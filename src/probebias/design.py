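"""Dot-probe and differential-conditioning schedule generation.

The dot-probe task presents two cues left/right of fixation for 100 or 500 ms,
then a probe at one cue's former location. Four conditions arise from pairing a
pain-conditioned threat cue (CS+), a safety cue (CS-), and a neutral cue (CSn):
CS+/CSn, CS-/CSn, CS+/CS-, and CSn/CSn. Conditioning pairs the CS+ with a
painful rectal distension (US) on a partial reinforcement schedule.

Schedules are fully counterbalanced (target side x probe side x stimulus
duration within each condition) and pseudo-randomized: no more than
``max_run`` consecutive trials share a condition (dot-probe) or a CS type
(conditioning). Generation is deterministic given an integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CS_PLUS = "CS+"
CS_MINUS = "CS-"
CS_NEUTRAL = "CSn"

COND_CSPLUS_NEUTRAL = "cs_plus_neutral"
COND_CSMINUS_NEUTRAL = "cs_minus_neutral"
COND_CSPLUS_CSMINUS = "cs_plus_cs_minus"
COND_NEUTRAL = "neutral"

CONDITIONS = (
    COND_CSPLUS_NEUTRAL,
    COND_CSMINUS_NEUTRAL,
    COND_CSPLUS_CSMINUS,
    COND_NEUTRAL,
)

#: cue shown at the designated target side / at the other side, per condition
_CONDITION_CUES = {
    COND_CSPLUS_NEUTRAL: (CS_PLUS, CS_NEUTRAL),
    COND_CSMINUS_NEUTRAL: (CS_MINUS, CS_NEUTRAL),
    COND_CSPLUS_CSMINUS: (CS_PLUS, CS_MINUS),
    COND_NEUTRAL: (CS_NEUTRAL, CS_NEUTRAL),
}

DEFAULT_CONDITION_COUNTS = {
    COND_CSPLUS_NEUTRAL: 80,
    COND_CSMINUS_NEUTRAL: 80,
    COND_CSPLUS_CSMINUS: 80,
    COND_NEUTRAL: 40,
}

SCHEDULE_COLUMNS = [
    "trial_index",
    "condition",
    "left_cue",
    "right_cue",
    "target_side",
    "duration_ms",
    "probe_side",
]


class InvalidDesignError(ValueError):
    """Requested trial counts cannot be balanced over the cell structure."""


@dataclass(frozen=True)
class TaskTimingConfig:
    """Per-trial timing constants of the dot-probe task, in milliseconds."""

    fixation_ms: float = 500.0
    stimulus_durations_ms: tuple[float, float] = (100.0, 500.0)
    blank_ms: float = 50.0
    max_response_ms: float = 2000.0
    iti_ms: float = 750.0

    def __post_init__(self) -> None:
        durations = tuple(self.stimulus_durations_ms)
        if len(durations) != 2:
            raise ValueError("stimulus_durations_ms must have exactly 2 members")
        for name in ("fixation_ms", "blank_ms", "max_response_ms", "iti_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(d <= 0 for d in durations):
            raise ValueError("stimulus durations must be > 0")


@dataclass(frozen=True)
class ConditioningSpec:
    """Differential delay-conditioning schedule parameters (durations in s)."""

    n_csplus: int = 16
    n_csminus: int = 16
    reinforcement_rate: float = 0.75
    us_duration_s: float = 16.0
    us_onset_window_s: tuple[float, float] = (6.0, 12.0)
    iti_s: float = 20.0
    max_run: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise ValueError("reinforcement_rate must lie in [0, 1]")
        lo, hi = self.us_onset_window_s
        if not 0 <= lo <= hi:
            raise ValueError("us_onset_window_s must be an ordered interval")
        if self.us_duration_s <= 0:
            raise ValueError("us_duration_s must be > 0")
        if self.n_csplus < 0 or self.n_csminus < 0:
            raise ValueError("CS counts must be non-negative")

    @property
    def n_reinforced(self) -> int:
        exact = self.reinforcement_rate * self.n_csplus
        if abs(exact - round(exact)) > 1e-9:
            raise ValueError(
                "reinforcement_rate x n_csplus is not integral; "
                "pass an explicit reinforced count via the rate"
            )
        return int(round(exact))


def _constrained_order(labels: np.ndarray, rng: np.random.Generator, max_run: int) -> np.ndarray:
    """Return a random permutation of ``labels`` with runs of equal labels <= max_run.

    Sequential sampling with restart on dead ends; with the trial mixes used
    here a dead end is rare, so a handful of restarts suffices.
    """
    uniq, counts = np.unique(labels, return_counts=True)
    if counts.max() > 0 and len(uniq) == 1 and len(labels) > max_run:
        raise InvalidDesignError("single-label sequence cannot satisfy the run constraint")
    for _ in range(1000):
        remaining = dict(zip(uniq.tolist(), counts.tolist()))
        out: list = []
        run_label, run_len = None, 0
        ok = True
        while len(out) < len(labels):
            choices = [
                lab
                for lab, c in remaining.items()
                if c > 0 and not (lab == run_label and run_len >= max_run)
            ]
            if not choices:
                ok = False
                break
            weights = np.array([remaining[lab] for lab in choices], dtype=float)
            lab = choices[rng.choice(len(choices), p=weights / weights.sum())]
            remaining[lab] -= 1
            out.append(lab)
            if lab == run_label:
                run_len += 1
            else:
                run_label, run_len = lab, 1
        if ok:
            return np.asarray(out)
    raise InvalidDesignError("could not satisfy the pseudo-randomization run constraint")


def build_dotprobe_schedule(
    timing: TaskTimingConfig | None = None,
    counts: dict[str, int] | None = None,
    seed: int = 0,
    max_run: int = 2,
) -> pd.DataFrame:
    """Build one counterbalanced, pseudo-randomized dot-probe run.

    Within each CS-containing condition every (target side x probe side x
    duration) cell receives ``counts[condition] / 8`` trials; the neutral
    condition balances (probe side x duration) in quarters. Trial order is a
    seeded permutation constrained to runs of at most ``max_run`` trials per
    condition.

    Returns a tidy frame with one row per trial (``SCHEDULE_COLUMNS``).
    """
    timing = timing or TaskTimingConfig()
    counts = dict(DEFAULT_CONDITION_COUNTS if counts is None else counts)
    unknown = set(counts) - set(CONDITIONS)
    if unknown:
        raise InvalidDesignError(f"unknown conditions: {sorted(unknown)}")
    durations = tuple(timing.stimulus_durations_ms)

    rows = []
    for cond in CONDITIONS:
        n = int(counts.get(cond, 0))
        if n == 0:
            continue
        target_cue, other_cue = _CONDITION_CUES[cond]
        if cond == COND_NEUTRAL:
            cells = list(itertools.product(["left", "right"], durations))
            if n % len(cells):
                raise InvalidDesignError(
                    f"{cond}: count {n} not divisible by {len(cells)} (probe side x duration)"
                )
            per_cell = n // len(cells)
            for probe_side, dur in cells:
                for _ in range(per_cell):
                    rows.append((cond, CS_NEUTRAL, CS_NEUTRAL, None, dur, probe_side))
        else:
            cells = list(itertools.product(["left", "right"], ["left", "right"], durations))
            if n % len(cells):
                raise InvalidDesignError(
                    f"{cond}: count {n} not divisible by {len(cells)} "
                    "(target side x probe side x duration)"
                )
            per_cell = n // len(cells)
            for target_side, probe_side, dur in cells:
                left, right = (
                    (target_cue, other_cue) if target_side == "left" else (other_cue, target_cue)
                )
                for _ in range(per_cell):
                    rows.append((cond, left, right, target_side, dur, probe_side))

    frame = pd.DataFrame(
        rows, columns=["condition", "left_cue", "right_cue", "target_side", "duration_ms", "probe_side"]
    )
    rng = np.random.default_rng(seed)
    order = _constrained_order(frame["condition"].to_numpy(), rng, max_run)
    # map the constrained condition sequence back to concrete trial rows,
    # shuffling within condition so cell assignment is also randomized
    out_indices = np.empty(len(frame), dtype=int)
    for cond in CONDITIONS:
        idx = frame.index[frame["condition"] == cond].to_numpy()
        rng.shuffle(idx)
        out_indices[np.flatnonzero(order == cond)] = idx
    frame = frame.iloc[out_indices].reset_index(drop=True)
    frame.insert(0, "trial_index", np.arange(len(frame)))
    return frame[SCHEDULE_COLUMNS]


def build_conditioning_schedule(spec: ConditioningSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Build the pseudo-randomized CS+/CS- conditioning sequence.

    Exactly ``round(n_csplus * reinforcement_rate)`` CS+ trials carry a US
    whose onset is drawn uniformly on the configured window; CS type runs are
    bounded by ``spec.max_run``.
    """
    spec = spec or ConditioningSpec()
    n_reinforced = spec.n_reinforced
    rng = np.random.default_rng(seed)
    labels = np.array([CS_PLUS] * spec.n_csplus + [CS_MINUS] * spec.n_csminus)
    order = _constrained_order(labels, rng, spec.max_run)
    reinforced = np.zeros(len(order), dtype=bool)
    plus_pos = np.flatnonzero(order == CS_PLUS)
    reinforced[rng.choice(plus_pos, size=n_reinforced, replace=False)] = True
    lo, hi = spec.us_onset_window_s
    onset = np.where(reinforced, rng.uniform(lo, hi, size=len(order)), np.nan)
    return pd.DataFrame(
        {
            "trial_index": np.arange(len(order)),
            "cs_type": order,
            "reinforced": reinforced,
            "us_onset_s": onset,
        }
    )


def dotprobe_run_duration_min(
    schedule: pd.DataFrame,
    timing: TaskTimingConfig | None = None,
    assumed_rt_ms: float = 2000.0,
) -> float:
    """Run duration in minutes from the package's own timing constants."""
    timing = timing or TaskTimingConfig()
    per_trial = (
        timing.fixation_ms
        + schedule["duration_ms"].to_numpy(float)
        + timing.blank_ms
        + assumed_rt_ms
        + timing.iti_ms
    )
    return float(per_trial.sum() / 60000.0)
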