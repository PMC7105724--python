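"""Recruitment-flow accounting and screening rules.

Tracks sequential exclusions from first contact to the analyzed sample
(entering(k+1) = entering(k) - excluded(k)) and applies the screening rules
as data filters on a subject table: HADS (anxiety or depression) >= 8,
gastrointestinal symptom score >= 13, and a tissue-damage exclusion flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: the study's flow from personal interview to the analyzed sample
STUDY_FLOW = [
    ("HADS >= 8", 5),
    ("gastrointestinal symptoms >= 13", 3),
    ("anal tissue damage", 1),
    ("missed appointment", 2),
    ("terminated during study", 1),
]
STUDY_INTERVIEWED = 76


@dataclass(frozen=True)
class FlowStage:
    label: str
    excluded: int


def apply_flow(initial: int, stages: list) -> tuple[int, pd.DataFrame]:
    """Sequentially subtract exclusions; errors on a negative running count.

    ``stages`` holds (label, excluded) pairs or :class:`FlowStage` items.
    Returns (final count, rendered flow table).
    """
    rows = []
    entering = int(initial)
    for stage in stages:
        label, excluded = (stage.label, stage.excluded) if isinstance(stage, FlowStage) else stage
        excluded = int(excluded)
        if excluded < 0:
            raise ValueError(f"negative exclusion count at {label!r}")
        remaining = entering - excluded
        if remaining < 0:
            raise ValueError(f"flow count goes negative at {label!r}")
        rows.append({"stage": label, "entering": entering, "excluded": excluded,
                     "remaining": remaining})
        entering = remaining
    return entering, pd.DataFrame(rows)


def screen_subjects(
    table: pd.DataFrame,
    hads_cutoff: float = 8.0,
    gi_cutoff: float = 13.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the screening rules to a subject table.

    Recognized columns (all optional): ``hads_anxiety``, ``hads_depression``,
    ``gi_symptoms``, ``tissue_damage`` (boolean). Returns (retained, log of
    per-rule exclusion counts applied sequentially).
    """
    df = table.copy()
    stages = []
    if {"hads_anxiety", "hads_depression"} & set(df.columns):
        hads = df.reindex(columns=["hads_anxiety", "hads_depression"]).max(axis=1)
        bad = hads >= hads_cutoff
        stages.append((f"HADS >= {hads_cutoff:g}", int(bad.sum())))
        df = df[~bad]
    if "gi_symptoms" in df.columns:
        bad = df["gi_symptoms"] >= gi_cutoff
        stages.append((f"gastrointestinal symptoms >= {gi_cutoff:g}", int(bad.sum())))
        df = df[~bad]
    if "tissue_damage" in df.columns:
        bad = df["tissue_damage"].astype(bool)
        stages.append(("anal tissue damage", int(bad.sum())))
        df = df[~bad]
    _, log = apply_flow(len(table), stages)
    return df, log
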