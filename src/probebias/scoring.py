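"""Attentional-bias indices and baseline-to-test change scores.

Three indices are computed from each subject's condition cell means:

    avoidance     = RT_incongruent - RT_congruent   (negative = avoidance)
    engagement    = RT_neutral - RT_congruent       (positive = capture)
    disengagement = RT_neutral - RT_incongruent     (negative = difficulty
                                                     disengaging)

The identity ``avoidance == engagement - disengagement`` holds exactly on
every cell because all three are formed from the same means. The CS+/CS-
condition is scored twice, once per designated target cue (CS+/CS- and
CS-/CS+ rows). Change scores are test minus baseline, by default averaged
over the two stimulus durations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import CS_LABELS, LABEL_NEUTRAL, MEAN_COLUMNS

INDEX_NAMES = ("avoidance", "engagement", "disengagement")


def avoidance_index(rt_congruent, rt_incongruent):
    """RT_incongruent - RT_congruent; negative scores = stronger avoidance."""
    return np.asarray(rt_incongruent, float) - np.asarray(rt_congruent, float)


def engagement_index(rt_congruent, rt_neutral):
    """RT_neutral - RT_congruent; positive scores = enhanced capture."""
    return np.asarray(rt_neutral, float) - np.asarray(rt_congruent, float)


def disengagement_index(rt_incongruent, rt_neutral):
    """RT_neutral - RT_incongruent; negative scores = stronger vigilance."""
    return np.asarray(rt_neutral, float) - np.asarray(rt_incongruent, float)


def score_indices(cells: pd.DataFrame, respect_outlier_flags: bool = True) -> pd.DataFrame:
    """Score all three indices per subject x phase x condition x duration.

    Neutral-only rows carry no target and are not scored. Cell means flagged
    by the outlier screen (``*_outlier`` columns, when present and
    ``respect_outlier_flags``) are treated as missing, propagating NaN into
    any index that uses them.
    """
    df = cells[cells["target_label"] != LABEL_NEUTRAL].copy()
    means = {}
    for col in MEAN_COLUMNS:
        vals = df[col].to_numpy(float).copy()
        flag_col = f"{col}_outlier"
        if respect_outlier_flags and flag_col in df:
            vals[df[flag_col].to_numpy(bool)] = np.nan
        means[col] = vals
    out = df[["subject_id", "phase", "target_label", "duration_ms"]].copy()
    out["avoidance"] = avoidance_index(means["rt_congruent"], means["rt_incongruent"])
    out["engagement"] = engagement_index(means["rt_congruent"], means["rt_neutral"])
    out["disengagement"] = disengagement_index(means["rt_incongruent"], means["rt_neutral"])
    return out.reset_index(drop=True)


def change_scores(indices: pd.DataFrame, collapse_durations: bool = True) -> pd.DataFrame:
    """Test-minus-baseline change per subject x condition (x duration).

    With ``collapse_durations`` (default) indices are first averaged over the
    stimulus durations within each phase; a change score is missing whenever
    either phase value is missing.
    """
    keys = ["subject_id", "target_label"] + ([] if collapse_durations else ["duration_ms"])
    value_cols = list(INDEX_NAMES)
    df = indices.copy()
    if collapse_durations:
        df = df.groupby(keys + ["phase"], observed=True)[value_cols].mean().reset_index()
    wide = df.pivot_table(
        index=keys, columns="phase", values=value_cols, aggfunc="first", observed=True,
        dropna=False,
    )
    out = pd.DataFrame(index=wide.index)
    for name in value_cols:
        try:
            out[f"delta_{name}"] = wide[(name, "test")] - wide[(name, "baseline")]
        except KeyError as exc:
            raise ValueError("change scores need both baseline and test phases") from exc
    return out.reset_index()


def index_summary_table(
    indices: pd.DataFrame, subjects: pd.DataFrame, collapse_durations: bool = True
) -> pd.DataFrame:
    """Group mean +/- SEM per condition x phase x sex, in report layout."""
    df = indices.merge(subjects[["subject_id", "sex"]], on="subject_id")
    keys = ["target_label", "phase", "sex"] + (
        [] if collapse_durations else ["duration_ms"]
    )
    if collapse_durations:
        df = (
            df.groupby(["subject_id", "sex", "target_label", "phase"], observed=True)[
                list(INDEX_NAMES)
            ]
            .mean()
            .reset_index()
        )
    grouped = df.groupby(keys, observed=True)[list(INDEX_NAMES)]
    mean = grouped.mean()
    sem = grouped.sem()
    n = grouped.count()
    out = pd.concat(
        {"mean": mean, "sem": sem, "n": n}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1)
    return out.reset_index()


class BiasIndexScorer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: cell means -> per-cell bias indices.

    With ``with_change_scores`` the output is the change-score table instead
    of per-phase indices.
    """

    def __init__(
        self,
        respect_outlier_flags: bool = True,
        with_change_scores: bool = False,
        collapse_durations: bool = True,
    ):
        self.respect_outlier_flags = respect_outlier_flags
        self.with_change_scores = with_change_scores
        self.collapse_durations = collapse_durations

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        indices = score_indices(X, self.respect_outlier_flags)
        self.indices_ = indices
        if self.with_change_scores:
            return change_scores(indices, self.collapse_durations)
        return indices
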