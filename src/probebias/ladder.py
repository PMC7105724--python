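"""Hierarchical block-entry moderation regressions ("the ladder").

Each candidate predictor of a bias-index change score is tested through a
fixed removal sequence of ordinary least-squares models:

1. full:      outcome ~ sex + predictor + sex*predictor
2. main_only: outcome ~ sex + predictor        (if the full model's overall
                                                F is not significant)
3. sex_only:  outcome ~ sex                    (if the main-only model is not
                                                significant either)

Sex is coded 0 = female, 1 = male (uncentered) and always retained; the
interaction is the raw product of the sex code and the predictor. The ladder
stops at the first model whose overall F-test is significant at alpha.
Standardized betas are reported as b_j * SD(x_j) / SD(y) (the interaction
standardized as the z-score of the product), so they may exceed 1 under
collinearity. When the final model's predictor main effect and/or interaction
coefficient is significant, per-sex follow-up regressions of the outcome on
the predictor are fitted and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

SEX_CODES = {"female": 0.0, "male": 1.0}

STAGES = ("full", "main_only", "sex_only")


class SingularModelError(ValueError):
    """A predictor column is collinear/degenerate; names the offending term."""


def standardize(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score every column; returns (z_frame, scaling) where scaling records
    the per-column mean and SD (ddof=1) for back-transformation."""
    means = frame.mean()
    sds = frame.std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise SingularModelError(f"zero-variance column(s): {zero}")
    scaling = pd.DataFrame({"mean": means, "sd": sds})
    return (frame - means) / sds, scaling


def destandardize(z_frame: pd.DataFrame, scaling: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`standardize`."""
    return z_frame * scaling["sd"] + scaling["mean"]


def _fit_ols(y: pd.Series, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResults:
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy(float)) < Xc.shape[1]:
        sds = X.std(ddof=0)
        bad = sds[sds == 0].index.tolist() or X.columns.tolist()
        raise SingularModelError(f"singular design; offending term(s): {bad}")
    return sm.OLS(y.to_numpy(float), Xc).fit()


def _coef_table(res, y: pd.Series, X: pd.DataFrame) -> pd.DataFrame:
    sd_y = y.std(ddof=1)
    rows = []
    for name in X.columns:
        b = res.params[name]
        beta = b * X[name].std(ddof=1) / sd_y if sd_y > 0 else np.nan
        rows.append(
            {
                "term": name,
                "b": float(b),
                "beta": float(beta),
                "t": float(res.tvalues[name]),
                "p": float(res.pvalues[name]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LadderResult:
    """Final model of the removal sequence plus optional per-sex follow-ups."""

    outcome: str
    predictors: tuple[str, ...]
    stage: str
    f: float
    p_model: float
    adj_r2: float
    coefficients: pd.DataFrame
    stage_p_values: dict = field(default_factory=dict)
    followups: pd.DataFrame | None = None

    def report(self) -> str:
        p = f"{self.p_model:.3f}".lstrip("0")
        r2 = f"{self.adj_r2:.2f}".lstrip("0").replace("-.", "-.")
        return f"F = {self.f:.2f}, p = {p}, adj. R2 = {r2} [{self.stage}]"


class ModerationLadder(BaseEstimator):
    """Sklearn-style estimator for the block-entry/removal regression ladder.

    ``predictors`` may hold one candidate (the usual ladder) or several (each
    contributes a main effect and a sex-interaction term to the full model and
    all interactions are removed before all main effects).
    """

    def __init__(
        self,
        outcome: str,
        predictors: list[str] | str,
        sex_col: str = "sex",
        alpha: float = 0.05,
    ):
        self.outcome = outcome
        self.predictors = predictors
        self.sex_col = sex_col
        self.alpha = alpha

    def fit(self, data: pd.DataFrame, y=None):
        predictors = (
            [self.predictors] if isinstance(self.predictors, str) else list(self.predictors)
        )
        cols = [self.outcome, self.sex_col] + predictors
        df = data[cols].dropna()
        if len(df) < 10:
            raise ValueError("the regression ladder needs >= 10 complete cases")
        sex = df[self.sex_col]
        if sex.dtype == object or str(sex.dtype) == "category":
            sex = sex.map(SEX_CODES)
            if sex.isna().any():
                raise ValueError(f"sex column must contain {sorted(SEX_CODES)}")
        X_all = pd.DataFrame({"sex": sex.to_numpy(float)}, index=df.index)
        for name in predictors:
            X_all[name] = df[name].to_numpy(float)
            X_all[f"sex*{name}"] = X_all["sex"] * X_all[name]
        y_series = df[self.outcome]

        stage_cols = {
            "full": list(X_all.columns),
            "main_only": ["sex"] + predictors,
            "sex_only": ["sex"],
        }
        stage_p: dict[str, float] = {}
        chosen = None
        for stage in STAGES:
            X = X_all[stage_cols[stage]]
            res = _fit_ols(y_series, X)
            stage_p[stage] = float(res.f_pvalue)
            if res.f_pvalue < self.alpha or stage == "sex_only":
                chosen = (stage, res, X)
                break
        stage, res, X = chosen
        coef = _coef_table(res, y_series, X)

        followups = None
        trigger_terms = coef[coef["term"] != "sex"]
        if stage != "sex_only" and (trigger_terms["p"] < self.alpha).any():
            rows = []
            for sex_label, code in SEX_CODES.items():
                sub = df[X_all["sex"] == code]
                for name in predictors:
                    yf = sub[self.outcome]
                    Xf = sub[[name]]
                    try:
                        rf = _fit_ols(yf, Xf)
                    except SingularModelError:
                        continue
                    cf = _coef_table(rf, yf, Xf).iloc[0]
                    rows.append(
                        {
                            "sex": sex_label,
                            "predictor": name,
                            "f": float(rf.fvalue),
                            "p": float(rf.f_pvalue),
                            "adj_r2": float(rf.rsquared_adj),
                            "beta": cf["beta"],
                            "t": cf["t"],
                        }
                    )
            followups = pd.DataFrame(rows)

        self.result_ = LadderResult(
            outcome=self.outcome,
            predictors=tuple(predictors),
            stage=stage,
            f=float(res.fvalue),
            p_model=float(res.f_pvalue),
            adj_r2=float(res.rsquared_adj),
            coefficients=coef,
            stage_p_values=stage_p,
            followups=followups,
        )
        return self


def run_ladder(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str] | str,
    sex_col: str = "sex",
    alpha: float = 0.05,
) -> LadderResult:
    """Functional wrapper over :class:`ModerationLadder`."""
    model = ModerationLadder(outcome, predictors, sex_col=sex_col, alpha=alpha)
    return model.fit(data).result_


def replay_stage(stage_p_values: dict, alpha: float = 0.05) -> str:
    """Pure transition rule: the stage reached given the logged model p-values."""
    for stage in STAGES:
        if stage not in stage_p_values:
            continue
        if stage_p_values[stage] < alpha or stage == "sex_only":
            return stage
    return "sex_only"
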