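"""Group comparisons: t-tests, mixed-design repeated-measures ANCOVA with
Greenhouse-Geisser correction, Bonferroni post-hocs, and the response-slowing
control analysis.

The ANCOVA uses the classical univariate (contrast) decomposition: subject x
within-cell data are projected onto orthonormal within-subject contrasts; each
projected column is regressed on the between-subjects design (intercept,
grand-mean-centered covariate, sum-coded between factor), and sums of squares
are pooled over columns. For a within-effect stratum with q contrast columns,
the Greenhouse-Geisser epsilon is estimated from the residual covariance S of
the projected scores as tr(S)^2 / (q * tr(S^2)) and multiplies both degrees of
freedom of the F test; a two-level factor has q = 1 and epsilon exactly 1.
Effect sizes are partial eta squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

ANOVA_COLUMNS = [
    "effect",
    "ss",
    "df1",
    "df2",
    "gg_epsilon",
    "F",
    "p_uncorrected",
    "p",
    "partial_eta_sq",
]


class SummaryStats(NamedTuple):
    """Published group summary: mean, standard error of the mean, group n."""

    mean: float
    sem: float
    n: int


def t_from_summary(g1: SummaryStats, g2: SummaryStats) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from printed mean/SEM/n summaries.

    SD is recovered as sem * sqrt(n); with equal n this reduces to
    ``t = (m1 - m2) / sqrt(sem1^2 + sem2^2)``. Returns (t, df, two-sided p).
    """
    g1, g2 = SummaryStats(*g1), SummaryStats(*g2)
    if g1.n < 2 or g2.n < 2:
        raise ValueError("summary t-test needs n >= 2 per group")
    var1, var2 = (g1.sem**2) * g1.n, (g2.sem**2) * g2.n
    df = g1.n + g2.n - 2
    pooled = ((g1.n - 1) * var1 + (g2.n - 1) * var2) / df
    se = np.sqrt(pooled * (1 / g1.n + 1 / g2.n))
    t = (g1.mean - g2.mean) / se
    return float(t), int(df), float(2 * stats.t.sf(abs(t), df))


def paired_t(values_a, values_b) -> tuple[float, int, float]:
    """Paired t-test; degenerate zero-variance differences are reported as
    signed-infinite t with p = 0 (or t = 0, p = 1 when all differences are 0).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired t needs two equal-length 1-d samples, n >= 2")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("paired t requires pairwise-complete data")
    d = a - b
    df = len(d) - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


def bonferroni(p_values, family_size: int | None = None):
    """Bonferroni adjustment min(1, k * p); k defaults to the vector length."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    k = family_size if family_size is not None else p.size
    return np.minimum(1.0, k * p)


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels x (levels-1)) orthonormal basis orthogonal to the unit vector."""
    full = np.column_stack([np.ones(levels), np.eye(levels)[:, : levels - 1]])
    q, _ = np.linalg.qr(full)
    q = q[:, 1:]
    for j in range(q.shape[1]):  # deterministic sign convention
        lead = q[np.flatnonzero(np.abs(q[:, j]) > 1e-12)[0], j]
        if lead < 0:
            q[:, j] = -q[:, j]
    return q


def _sum_code(series: pd.Series, levels: list) -> np.ndarray:
    """Sum (deviation) coding: L-1 columns, last level as the negative base."""
    n, L = len(series), len(levels)
    X = np.zeros((n, L - 1))
    for j, lev in enumerate(levels[:-1]):
        X[:, j] = (series == lev).astype(float)
    X[(series == levels[-1]).to_numpy()] = -1.0
    return X


class MixedAnova(BaseEstimator):
    """Mixed-design repeated-measures AN(C)OVA, sklearn estimator style.

    Parameters
    ----------
    dv : response column (one observation per subject x within-cell).
    within : list of within-subject factor columns (fully crossed).
    between : optional between-subjects factor column.
    covariate : optional numeric subject-level covariate, grand-mean centered
        before entering every stratum (homogeneous slope; no covariate x
        between interaction term).
    subject : subject identifier column.

    After ``fit``, ``anova_`` holds one row per effect with uncorrected df,
    Greenhouse-Geisser epsilon, F, GG-corrected p (within effects) and
    partial eta squared; ``n_subjects_`` and ``dropped_subjects_`` record
    listwise deletion of subjects with incomplete within-cells.
    """

    def __init__(
        self,
        dv: str,
        within: list[str],
        between: str | None = None,
        covariate: str | None = None,
        subject: str = "subject_id",
    ):
        self.dv = dv
        self.within = within
        self.between = between
        self.covariate = covariate
        self.subject = subject

    def fit(self, data: pd.DataFrame, y=None):
        within = list(self.within)
        if not within:
            raise ValueError("at least one within-subject factor is required")
        dup = data.duplicated(subset=[self.subject] + within)
        if dup.any():
            raise ValueError("multiple observations per subject x within-cell")

        levels = {f: sorted(data[f].dropna().unique().tolist()) for f in within}
        wide = data.pivot(index=self.subject, columns=within, values=self.dv)
        full_cols = (
            pd.MultiIndex.from_product([levels[f] for f in within], names=within)
            if len(within) > 1
            else pd.Index(levels[within[0]], name=within[0])
        )
        wide = wide.reindex(columns=full_cols)
        complete = wide.notna().all(axis=1)
        if not complete.all():
            warnings.warn(
                f"dropping {(~complete).sum()} subject(s) with incomplete within-cells",
                stacklevel=2,
            )
        self.dropped_subjects_ = wide.index[~complete].tolist()
        wide = wide[complete]
        Y = wide.to_numpy(float)
        n = len(wide)

        # between-subjects design
        subj_info = (
            data.drop_duplicates(self.subject).set_index(self.subject).loc[wide.index]
        )
        X_parts: list[np.ndarray] = [np.ones((n, 1))]
        term_slices: dict[str, slice] = {}
        col = 1
        covariate = self.covariate
        if covariate is not None:
            cov = subj_info[covariate].to_numpy(float)
            if np.ptp(cov) == 0:
                warnings.warn("constant covariate dropped", stacklevel=2)
                covariate = None
            else:
                X_parts.append((cov - cov.mean()).reshape(-1, 1))
                term_slices[covariate] = slice(col, col + 1)
                col += 1
        if self.between is not None:
            blevels = sorted(subj_info[self.between].dropna().unique().tolist())
            if len(blevels) < 2:
                raise ValueError("between factor needs >= 2 levels")
            Xb = _sum_code(subj_info[self.between], blevels)
            X_parts.append(Xb)
            term_slices[self.between] = slice(col, col + Xb.shape[1])
            col += Xb.shape[1]
        X = np.hstack(X_parts)
        p = X.shape[1]
        if n - p < 1:
            raise ValueError("not enough subjects for the between-subjects design")

        contrasts = {f: _orthonormal_contrasts(len(levels[f])) for f in within}
        unit = {f: np.ones((len(levels[f]), 1)) / np.sqrt(len(levels[f])) for f in within}

        rows = []
        for r in range(len(within) + 1):
            for subset in itertools.combinations(within, r):
                M = np.ones((1, 1))
                for f in within:
                    M = np.kron(M, contrasts[f] if f in subset else unit[f])
                Z = Y @ M
                q = Z.shape[1]
                beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
                resid = Z - X @ beta
                rss_full = (resid**2).sum(axis=0)
                ss_error = float(rss_full.sum())
                df_error = q * (n - p)
                S = resid.T @ resid / (n - p)
                if subset and q > 1:
                    eps = float(np.trace(S) ** 2 / (q * np.trace(S @ S)))
                    eps = min(1.0, max(eps, 1.0 / q))
                else:
                    eps = 1.0

                terms: list[tuple[str, np.ndarray]] = []
                if subset:
                    terms.append((" x ".join(subset), np.array([0])))  # intercept stratum
                for name, sl in term_slices.items():
                    label = " x ".join(subset + (name,)) if subset else name
                    terms.append((label, np.arange(p)[sl]))
                for label, cols_idx in terms:
                    keep = np.setdiff1d(np.arange(p), cols_idx)
                    X_red = X[:, keep]
                    if X_red.shape[1]:
                        beta_r, *_ = np.linalg.lstsq(X_red, Z, rcond=None)
                        rss_red = ((Z - X_red @ beta_r) ** 2).sum(axis=0)
                    else:
                        rss_red = (Z**2).sum(axis=0)
                    ss = float((rss_red - rss_full).sum())
                    df1 = q * len(cols_idx)
                    F = (ss / df1) / (ss_error / df_error)
                    p_unc = float(stats.f.sf(F, df1, df_error))
                    p_gg = (
                        float(stats.f.sf(F, df1 * eps, df_error * eps)) if subset else p_unc
                    )
                    rows.append(
                        {
                            "effect": label,
                            "ss": ss,
                            "df1": df1,
                            "df2": df_error,
                            "gg_epsilon": eps if subset else np.nan,
                            "F": float(F),
                            "p_uncorrected": p_unc,
                            "p": p_gg,
                            "partial_eta_sq": ss / (ss + ss_error),
                            "ss_error": ss_error,
                        }
                    )
        self.anova_ = pd.DataFrame(rows)[ANOVA_COLUMNS + ["ss_error"]]
        self.n_subjects_ = n
        return self

    def effect(self, name: str) -> pd.Series:
        """Row of ``anova_`` for one effect label (e.g. ``"phase x sex"``)."""
        tab = self.anova_
        hit = tab[tab["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect {name!r}; available: {tab['effect'].tolist()}")
        return hit.iloc[0]


def rm_ancova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    between: str | None = None,
    covariate: str | None = None,
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Functional wrapper over :class:`MixedAnova`; returns the ANOVA table."""
    model = MixedAnova(dv, within, between, covariate, subject)
    return model.fit(data).anova_


def _adjust_for_covariate(df: pd.DataFrame, dv: str, covariate: str | None) -> pd.Series:
    if covariate is None:
        return df[dv]
    cov = df[covariate].to_numpy(float)
    c = cov - cov.mean()
    if np.ptp(c) == 0:
        return df[dv]
    y = df[dv].to_numpy(float)
    slope = float(np.dot(c, y - y.mean()) / np.dot(c, c))
    return pd.Series(y - slope * c, index=df.index)


def posthoc_pairwise(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    by: str | None = None,
    kind: str = "between",
    subject: str = "subject_id",
    covariate: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise contrasts decomposing an interaction.

    ``kind='between'`` compares the two levels of a between factor with a
    two-sample t (on covariate-adjusted values when ``covariate`` is given);
    ``kind='within'`` uses a paired t per subject. ``by`` slices the data into
    the strata whose contrasts form the family (family size = number of
    contrasts actually computed).
    """
    if kind not in ("between", "within"):
        raise ValueError("kind must be 'between' or 'within'")
    strata = [(None, data)] if by is None else list(data.groupby(by, observed=True))
    rows = []
    for stratum, df in strata:
        df = df.copy()
        df[dv] = _adjust_for_covariate(df, dv, covariate)
        levs = sorted(df[factor].dropna().unique().tolist())
        for la, lb in itertools.combinations(levs, 2):
            a = df[df[factor] == la]
            b = df[df[factor] == lb]
            if kind == "between":
                t, pval = stats.ttest_ind(a[dv], b[dv])
                diff = a[dv].mean() - b[dv].mean()
            else:
                merged = a.set_index(subject)[dv].to_frame("a").join(
                    b.set_index(subject)[dv].to_frame("b"), how="inner"
                ).dropna()
                t, _, pval = paired_t(merged["a"], merged["b"])
                diff = float((merged["a"] - merged["b"]).mean())
            rows.append(
                {
                    "stratum": stratum,
                    "contrast": f"{la} vs {lb}",
                    "mean_diff": float(diff),
                    "t": float(t),
                    "p_raw": float(pval),
                }
            )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p_raw"], family_size=len(out))
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def response_slowing_test(
    cells: pd.DataFrame,
    subjects: pd.DataFrame,
    duration_ms: float,
    phase: str = "test",
    between: str | None = "sex",
    covariate: str | None = "bmi",
) -> pd.DataFrame:
    """Cue (CS+/CSn vs CSn/CSn) x congruency ANCOVA on raw cell-mean RTs at
    one stimulus duration, testing response slowing as a confound.

    The neutral-only condition contributes its pseudo-congruency split (probe
    at the left-placed vs right-placed cue). Returns the ANOVA table; the
    ``cue x congruency`` row is the effect of interest.
    """
    from .preprocess import LABEL_CSPLUS_N, LABEL_NEUTRAL

    sub = cells[
        (cells["duration_ms"] == duration_ms)
        & (cells["phase"] == phase)
        & (cells["target_label"].isin([LABEL_CSPLUS_N, LABEL_NEUTRAL]))
    ]
    if sub["target_label"].nunique() < 2:
        raise ValueError("both the CS+/CSn and CSn/CSn conditions are required")
    long = sub.melt(
        id_vars=["subject_id", "target_label"],
        value_vars=["rt_congruent", "rt_incongruent"],
        var_name="congruency",
        value_name="rt",
    )
    long["congruency"] = long["congruency"].str.replace("rt_", "", regex=False)
    long["cue"] = np.where(long["target_label"] == LABEL_CSPLUS_N, "cs_plus", "neutral")
    cols = ["subject_id"] + [c for c in (between, covariate) if c is not None]
    long = long.merge(subjects[cols], on="subject_id", how="left")
    if long["subject_id"].nunique() < 2:
        raise ValueError("response-slowing test needs >= 2 subjects")
    model = MixedAnova(
        "rt", within=["cue", "congruency"], between=between, covariate=covariate
    )
    model.fit(long)
    return model.anova_


def format_effect(row: pd.Series) -> str:
    """Human-readable report line, e.g. ``F = 7.80, p = .007, eta2 = .14``."""
    p = f"{row['p']:.3f}".lstrip("0")
    eta = f"{row['partial_eta_sq']:.2f}".lstrip("0")
    return f"F = {row['F']:.2f}, p = {p}, eta2 = {eta}"
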