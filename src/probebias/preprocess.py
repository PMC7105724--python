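"""Trial filtering, cell-mean aggregation and IQR outlier screening.

Cleaning follows the standard dot-probe recommendations: premature responses
(< 100 ms), missing responses and false responses (wrong side) are removed
before averaging. Cell means are then formed per subject x phase x condition
x stimulus duration and congruency via the side-cell formulas

    RT_congruent   = (RT_tldl + RT_trdr) / 2
    RT_incongruent = (RT_tldr + RT_trdl) / 2
    RT_neutral     = (RT_tldl + RT_trdr + RT_tldr + RT_trdl) / 4

(t = target side, d = dot side; with balanced cells these equal the plain
trial means). Outlying subject-level cell means are flagged across subjects
within each phase x condition x duration x congruency cell using Tukey
fences Q1 - 1.5*IQR and Q3 + 1.5*IQR, in a single pass.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .design import (
    COND_CSPLUS_CSMINUS,
    COND_CSMINUS_NEUTRAL,
    COND_CSPLUS_NEUTRAL,
    COND_NEUTRAL,
)

#: report labels: designated target cue / accompanying cue
LABEL_CSPLUS_N = "CS+/CSn"
LABEL_CSMINUS_N = "CS-/CSn"
LABEL_CSPLUS_CSMINUS = "CS+/CS-"
LABEL_CSMINUS_CSPLUS = "CS-/CS+"
LABEL_NEUTRAL = "CSn/CSn"

CS_LABELS = (LABEL_CSPLUS_N, LABEL_CSMINUS_N, LABEL_CSPLUS_CSMINUS, LABEL_CSMINUS_CSPLUS)

CELL_KEYS = ["subject_id", "phase", "target_label", "duration_ms"]
MEAN_COLUMNS = ["rt_congruent", "rt_incongruent", "rt_neutral"]


class SchemaError(ValueError):
    """Input trial records violate the documented schema."""


def filter_trials(
    records: pd.DataFrame,
    premature_cutoff_ms: float = 100.0,
    max_rt_ms: float = 2000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove premature, missing and false responses.

    Returns ``(retained, exclusion_log)``; the log holds per subject x phase
    counts of each category and always sums to the input count. The premature
    boundary is strict: rt == 100 ms is retained. RTs above ``max_rt_ms`` are
    a schema violation (the task runtime caps responses at 2,000 ms).
    """
    rt = records["rt_ms"]
    if (rt > max_rt_ms).any():
        raise SchemaError(f"rt_ms above the {max_rt_ms:g} ms response cap")
    missing = rt.isna() | records["response_side"].isna()
    if ((rt <= 0) & ~missing).any():
        raise SchemaError("non-missing rt_ms must be positive")
    premature = ~missing & (rt < premature_cutoff_ms)
    false = ~missing & ~premature & (records["response_side"] != records["probe_side"])
    retained_mask = ~(missing | premature | false)

    category = np.select(
        [missing, premature, false], ["missing", "premature", "false"], default="retained"
    )
    log = (
        pd.DataFrame(
            {
                "subject_id": records["subject_id"],
                "phase": records["phase"],
                "category": pd.Categorical(
                    category, categories=["premature", "missing", "false", "retained"]
                ),
            }
        )
        .groupby(["subject_id", "phase", "category"], observed=False)
        .size()
        .unstack("category")
        .reset_index()
    )
    log.columns.name = None
    log["total"] = log[["premature", "missing", "false", "retained"]].sum(axis=1)
    return records[retained_mask].copy(), log


def _grouped_means(long: pd.DataFrame, keys: list[str], side_col: str, method: str) -> pd.DataFrame:
    """Per-group mean RT and trial count; ``side_cell`` averages per-side means."""
    if method == "trial_weighted":
        out = (
            long.groupby(keys, observed=True)["rt_ms"]
            .agg(rt="mean", n="size")
            .reset_index()
        )
    else:
        per_side = (
            long.groupby(keys + [side_col], observed=True)["rt_ms"]
            .agg(["mean", "size"])
            .reset_index()
        )
        out = (
            per_side.groupby(keys, observed=True)
            .agg(rt=("mean", "mean"), n=("size", "sum"))
            .reset_index()
        )
    out["n"] = out["n"].astype(int)
    return out


def aggregate_cell_means(
    retained: pd.DataFrame, method: str = "side_cell"
) -> pd.DataFrame:
    """Aggregate retained trials to per-cell congruent/incongruent/neutral means.

    Each CS-containing condition yields one row per subject x phase x
    duration under its target label; the CS+/CS- condition is aggregated
    twice (CS+ designated target, then CS-), and neutral-only trials provide
    ``rt_neutral`` (per duration) joined onto every row, plus a ``CSn/CSn``
    row whose congruent/incongruent columns hold the pseudo-congruency split
    (probe replacing the left-placed vs right-placed cue) used by the
    response-slowing control analysis.

    ``method='side_cell'`` (default) applies the printed two-cell formulas;
    ``'trial_weighted'`` uses plain trial means. Empty cells yield NaN means,
    never silent zeros.
    """
    if method not in ("side_cell", "trial_weighted"):
        raise ValueError("method must be 'side_cell' or 'trial_weighted'")
    df = retained.copy()

    # expand to (target_label, congruent) rows
    parts = []
    for cond, label, flip in (
        (COND_CSPLUS_NEUTRAL, LABEL_CSPLUS_N, False),
        (COND_CSMINUS_NEUTRAL, LABEL_CSMINUS_N, False),
        (COND_CSPLUS_CSMINUS, LABEL_CSPLUS_CSMINUS, False),
        (COND_CSPLUS_CSMINUS, LABEL_CSMINUS_CSPLUS, True),
    ):
        sub = df[df["condition"] == cond].copy()
        congruent = sub["probe_side"] == sub["target_side"]
        sub["congruent"] = congruent ^ flip
        # the designated target side flips with the designation
        if flip:
            sub["target_side"] = np.where(sub["target_side"] == "left", "right", "left")
        sub["target_label"] = label
        parts.append(sub)
    neutral = df[df["condition"] == COND_NEUTRAL].copy()
    neutral["target_label"] = LABEL_NEUTRAL
    # pseudo-congruency: left-placed cue is the notional target
    neutral["congruent"] = neutral["probe_side"] == "left"
    neutral["target_side"] = "left"
    parts.append(neutral)
    long = pd.concat(parts, ignore_index=True)

    per_cell = _grouped_means(long, CELL_KEYS + ["congruent"], "target_side", method)
    agg = per_cell.set_index(CELL_KEYS + ["congruent"]).unstack("congruent")
    agg.columns = [f"{a}_{'congruent' if b else 'incongruent'}" for a, b in agg.columns]
    agg = agg.reset_index()
    for col in ("rt_congruent", "rt_incongruent"):
        if col not in agg:
            agg[col] = np.nan
    for col in ("n_congruent", "n_incongruent"):
        if col not in agg:
            agg[col] = 0
        agg[col] = agg[col].fillna(0).astype(int)

    # neutral reference mean per subject x phase x duration (all neutral trials)
    neut = _grouped_means(
        neutral, ["subject_id", "phase", "duration_ms"], "probe_side", method
    ).rename(columns={"rt": "rt_neutral", "n": "n_neutral"})
    out = agg.merge(neut, on=["subject_id", "phase", "duration_ms"], how="left")
    out["n_neutral"] = out["n_neutral"].fillna(0).astype(int)
    order = pd.CategoricalDtype(list(CS_LABELS) + [LABEL_NEUTRAL], ordered=True)
    out["target_label"] = out["target_label"].astype(order)
    return out.sort_values(CELL_KEYS).reset_index(drop=True)


def iqr_outlier_bounds(
    values, multiplier: float = 1.5, quartile_method: str = "linear"
) -> tuple[float, float]:
    """Tukey fences (Q1 - m*IQR, Q3 + m*IQR) over at least 4 values.

    Quartiles use linear interpolation between order statistics by default.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 4:
        raise ValueError("IQR bounds need at least 4 values")
    q1, q3 = np.percentile(arr, [25, 75], method=quartile_method)
    iqr = q3 - q1
    return float(q1 - multiplier * iqr), float(q3 + multiplier * iqr)


def apply_outlier_policy(
    cells: pd.DataFrame,
    multiplier: float = 1.5,
    quartile_method: str = "linear",
    scope: str = "cellwise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag subject-level cell means strictly outside the across-subject
    Tukey fences, computed within each phase x condition x duration x
    congruency cell, in exactly one pass.

    Returns ``(cells_with_flags, bounds_log)``. ``scope='cellwise'`` flags
    individual means (``<col>_outlier`` boolean columns); ``'listwise'``
    escalates any flag to all of that subject's rows.
    """
    if scope not in ("cellwise", "listwise"):
        raise ValueError("scope must be 'cellwise' or 'listwise'")
    out = cells.copy()
    bounds_rows = []
    for col in MEAN_COLUMNS:
        flag_col = f"{col}_outlier"
        out[flag_col] = False
        for key, grp in out.groupby(["phase", "target_label", "duration_ms"], observed=True):
            vals = grp[col].to_numpy(float)
            if np.isnan(vals).all():
                continue
            try:
                lo, hi = iqr_outlier_bounds(vals, multiplier, quartile_method)
            except ValueError:
                continue
            flagged = (grp[col] < lo) | (grp[col] > hi)
            out.loc[grp.index[flagged], flag_col] = True
            bounds_rows.append((*key, col, lo, hi, int(flagged.sum())))
    if scope == "listwise":
        flag_cols = [f"{c}_outlier" for c in MEAN_COLUMNS]
        bad_subjects = out.loc[out[flag_cols].any(axis=1), "subject_id"].unique()
        out.loc[out["subject_id"].isin(bad_subjects), flag_cols] = True
    bounds = pd.DataFrame(
        bounds_rows,
        columns=["phase", "target_label", "duration_ms", "column", "lower", "upper", "n_flagged"],
    )
    return out, bounds


def transform_valence(raw_mm):
    """Map a 0-200 mm VAS mark to the -100..+100 valence scale.

    Convention: 0 mm = very pleasant (-100), 100 mm = neutral (0),
    200 mm = very unpleasant (+100); the mapping is ``raw - 100``.
    """
    arr = np.asarray(raw_mm, dtype=float)
    if np.any((arr < 0) | (arr > 200)):
        raise ValueError("raw VAS values must lie in [0, 200] mm")
    out = arr - 100.0
    return float(out) if np.isscalar(raw_mm) else out


class TrialFilter(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper around :func:`filter_trials`.

    After ``transform``, ``exclusion_log_`` holds the per subject x phase
    category counts.
    """

    def __init__(self, premature_cutoff_ms: float = 100.0, max_rt_ms: float = 2000.0):
        self.premature_cutoff_ms = premature_cutoff_ms
        self.max_rt_ms = max_rt_ms

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        retained, log = filter_trials(X, self.premature_cutoff_ms, self.max_rt_ms)
        self.exclusion_log_ = log
        return retained


class CellMeanAggregator(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper around :func:`aggregate_cell_means`."""

    def __init__(self, method: str = "side_cell"):
        self.method = method

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return aggregate_cell_means(X, method=self.method)


class IQROutlierScreen(TransformerMixin, BaseEstimator):
    """Single-pass Tukey-fence screening of subject-level cell means.

    ``fit`` computes across-subject bounds per design cell (``bounds_``);
    ``transform`` adds ``*_outlier`` flags.
    """

    def __init__(
        self, multiplier: float = 1.5, quartile_method: str = "linear", scope: str = "cellwise"
    ):
        self.multiplier = multiplier
        self.quartile_method = quartile_method
        self.scope = scope

    def fit(self, X: pd.DataFrame, y=None):
        _, self.bounds_ = apply_outlier_policy(
            X, self.multiplier, self.quartile_method, self.scope
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        flagged, self.bounds_ = apply_outlier_policy(
            X, self.multiplier, self.quartile_method, self.scope
        )
        return flagged
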