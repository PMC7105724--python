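"""Synthetic cohort generation with injectable attentional-bias structure.

Subjects are drawn per sex from mean-corrected truncated normals whose
defaults reproduce the study sample's summary statistics (SD recovered from
SEM at n = 32 per sex). Trial-level reaction times follow an ex-Gaussian
(Gaussian + exponential tail), the standard empirical RT family, around a
latent per-trial mean into which attentional-bias effects are injected on the
population cell means:

    congruent-cell mean   = neutral mean - E   (engagement shift)
    incongruent-cell mean = neutral mean - D   (disengagement shift)

so that the scored indices (engagement = RT_neutral - RT_congruent,
disengagement = RT_neutral - RT_incongruent, avoidance = engagement -
disengagement) recover the injected E, D and E - D in expectation, making
parameter recovery exact and testable. Effects may additionally depend
linearly on a z-scored subject trait (sex-specific moderation), which is how
sex x trait interaction structure is injected for the regression ladder.

Premature (< 100 ms), missing and false responses occur as mutually exclusive
per-trial events with configurable rates, reproducing the filter categories
of the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import (
    COND_CSPLUS_CSMINUS,
    COND_CSMINUS_NEUTRAL,
    COND_CSPLUS_NEUTRAL,
    COND_NEUTRAL,
    CS_MINUS,
    CS_PLUS,
    CS_NEUTRAL,
)

_SQRT_N32 = np.sqrt(32.0)

#: per-sex (mean, SD) defaults; SD = SEM * sqrt(32) from the sample table
DEFAULT_COVARIATES = {
    "female": {
        "bmi": (21.92, 0.41 * _SQRT_N32),
        "stai_t": (36.75, 1.35 * _SQRT_N32),
        "panas_pos": (3.27, 0.12 * _SQRT_N32),
        "panas_neg": (1.41, 0.09 * _SQRT_N32),
        "prss_cat": (0.77, 0.17 * _SQRT_N32),
        "prss_cope": (3.57, 0.14 * _SQRT_N32),
        "pain_threshold": (38.04, 1.90 * _SQRT_N32),
    },
    "male": {
        "bmi": (23.66, 0.47 * _SQRT_N32),
        "stai_t": (34.59, 1.16 * _SQRT_N32),
        "panas_pos": (3.24, 0.11 * _SQRT_N32),
        "panas_neg": (1.37, 0.08 * _SQRT_N32),
        "prss_cat": (0.83, 0.12 * _SQRT_N32),
        "prss_cope": (3.52, 0.15 * _SQRT_N32),
        "pain_threshold": (40.34, 1.75 * _SQRT_N32),
    },
}

#: hard ranges per covariate: BMI is the study's inclusion window, the rest
#: are instrument score ranges (STAI-T 20-80, PANAS 1-5, PRSS 0-5, barostat
#: pressures 5-50 mmHg)
COVARIATE_BOUNDS = {
    "bmi": (18.0, 30.0),
    "stai_t": (20.0, 80.0),
    "panas_pos": (1.0, 5.0),
    "panas_neg": (1.0, 5.0),
    "prss_cat": (0.0, 5.0),
    "prss_cope": (0.0, 5.0),
    "pain_threshold": (5.0, 50.0),
}

PHASES = ("baseline", "test")

TRIAL_COLUMNS = [
    "subject_id",
    "sex",
    "phase",
    "trial_index",
    "condition",
    "left_cue",
    "right_cue",
    "target_side",
    "duration_ms",
    "probe_side",
    "response_side",
    "rt_ms",
]


@dataclass(frozen=True)
class RTNoiseParams:
    """Ex-Gaussian RT noise and per-trial response-failure rates.

    ``mu_ms``/``sigma_ms`` parameterize the Gaussian component, ``tau_ms`` the
    exponential tail; defaults put condition means in the plausible dot-probe
    range (~400-450 ms).
    """

    mu_ms: float = 350.0
    sigma_ms: float = 40.0
    tau_ms: float = 60.0
    premature_rate: float = 0.02
    false_rate: float = 0.02
    miss_rate: float = 0.01
    max_response_ms: float = 2000.0

    def __post_init__(self) -> None:
        if self.sigma_ms <= 0:
            raise ValueError("sigma_ms must be > 0")
        if self.tau_ms < 0:
            raise ValueError("tau_ms must be >= 0")
        rates = (self.premature_rate, self.false_rate, self.miss_rate)
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("failure rates must lie in [0, 1] and sum to < 1")

    @property
    def rt_var(self) -> float:
        """Trial-to-trial RT variance, sigma^2 + tau^2."""
        return self.sigma_ms**2 + self.tau_ms**2


@dataclass(frozen=True)
class EffectEntry:
    """One injected bias effect, matched by phase/condition/duration/sex.

    ``engagement_ms``/``disengagement_ms`` are constant shifts E and D;
    ``trait`` with ``engagement_slope_ms``/``disengagement_slope_ms`` adds a
    per-subject modulation of ``slope * z(trait)`` (z against the generating
    per-sex covariate distribution).
    """

    phase: str = "both"
    condition: str = "all"
    duration_ms: float | str = "both"
    sex: str = "both"
    engagement_ms: float = 0.0
    disengagement_ms: float = 0.0
    trait: str | None = None
    engagement_slope_ms: float = 0.0
    disengagement_slope_ms: float = 0.0

    def matches(self, phase: str, condition: str, duration: float, sex: str) -> bool:
        return (
            self.phase in ("both", phase)
            and self.condition in ("all", condition)
            and (self.duration_ms == "both" or float(self.duration_ms) == float(duration))
            and self.sex in ("both", sex)
        )


@dataclass(frozen=True)
class BiasEffectMap:
    """Collection of injected effects; the all-zero map is the null model."""

    entries: tuple[EffectEntry, ...] = ()

    @classmethod
    def null(cls) -> "BiasEffectMap":
        return cls(())

    @classmethod
    def from_dicts(cls, specs: list[dict]) -> "BiasEffectMap":
        return cls(tuple(EffectEntry(**s) for s in specs))

    def shifts(
        self,
        phase: str,
        condition: str,
        duration: float,
        sex: str,
        trait_z: dict[str, float] | None = None,
    ) -> tuple[float, float]:
        """Total (E, D) in ms for one design cell and subject."""
        e = d = 0.0
        for entry in self.entries:
            if not entry.matches(phase, condition, duration, sex):
                continue
            e += entry.engagement_ms
            d += entry.disengagement_ms
            if entry.trait is not None and trait_z is not None:
                z = trait_z.get(entry.trait, 0.0)
                e += entry.engagement_slope_ms * z
                d += entry.disengagement_slope_ms * z
        return e, d


@dataclass(frozen=True)
class RatingEffectParams:
    """Conditioning-induced valence shifts and contingency rating structure.

    Valence is on the -100 (very pleasant) .. +100 (very unpleasant) scale;
    baseline ratings for every cue center at 0. Shifts apply from
    post-conditioning onward (persisting through the test phase, matching the
    observed pattern). Contingency means/SDs default to the study's per-sex
    summary statistics.
    """

    csplus_valence_shift: float = 40.0
    csminus_valence_shift: float = -30.0
    rating_noise_sd: float = 15.0
    contingency_means: dict = field(
        default_factory=lambda: {
            ("female", CS_PLUS): 77.41,
            ("female", CS_MINUS): 15.69,
            ("male", CS_PLUS): 81.63,
            ("male", CS_MINUS): 11.41,
        }
    )
    contingency_sds: dict = field(
        default_factory=lambda: {
            ("female", CS_PLUS): 2.46 * _SQRT_N32,
            ("female", CS_MINUS): 3.63 * _SQRT_N32,
            ("male", CS_PLUS): 2.18 * _SQRT_N32,
            ("male", CS_MINUS): 3.46 * _SQRT_N32,
        }
    )

    def __post_init__(self) -> None:
        for shift in (self.csplus_valence_shift, self.csminus_valence_shift):
            if not -200 <= shift <= 200:
                raise ValueError("valence shifts must stay on the -100..100 scale")
        for m in self.contingency_means.values():
            if not 0 <= m <= 100:
                raise ValueError("contingency means must lie in [0, 100]")


import functools


@functools.lru_cache(maxsize=256)
def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose (lo, hi)-truncated normal has the target mean."""

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside bounds ({lo}, {hi})")
    return optimize.brentq(
        lambda loc: trunc_mean(loc) - target_mean, target_mean - 6 * sd, target_mean + 6 * sd
    )


def sample_cohort(
    n_per_sex: int = 32,
    covariate_config: dict | None = None,
    rt_base_sd_ms: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a balanced cohort of subject profiles.

    Covariates are sampled from truncated normals whose location is corrected
    so the *truncated* mean equals the configured mean — per-sex sample means
    therefore converge to the configured values as n grows while respecting
    instrument ranges and the BMI inclusion window. ``rt_base_ms`` is a
    subject-level mean-RT offset, N(0, ``rt_base_sd_ms``).
    """
    if n_per_sex < 2:
        raise ValueError("n_per_sex must be >= 2 (group inference needs >= 2 per sex)")
    config = covariate_config or DEFAULT_COVARIATES
    rng = np.random.default_rng(seed)
    frames = []
    for sex in ("female", "male"):
        n = n_per_sex
        cols: dict[str, np.ndarray] = {}
        for name, (mean, sd) in config[sex].items():
            lo, hi = COVARIATE_BOUNDS.get(name, (-np.inf, np.inf))
            if sd == 0:
                cols[name] = np.full(n, float(mean))
                continue
            loc = _truncnorm_loc(mean, sd, lo, hi) if np.isfinite(lo) or np.isfinite(hi) else mean
            a, b = (lo - loc) / sd, (hi - loc) / sd
            cols[name] = stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
        frame = pd.DataFrame(cols)
        frame.insert(0, "sex", sex)
        frame["rt_base_ms"] = rng.normal(0.0, rt_base_sd_ms, size=n)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"s{i + 1:03d}" for i in range(len(out))])
    return out


@functools.lru_cache(maxsize=256)
def _trait_moments(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of the mean-corrected truncated normal actually sampled."""
    if sd == 0:
        return mean, 0.0
    if not (np.isfinite(lo) or np.isfinite(hi)):
        return mean, sd
    loc = _truncnorm_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return mean, float(stats.truncnorm.std(a, b, loc=loc, scale=sd))


def _trait_z(subject: pd.Series, config: dict | None = None) -> dict[str, float]:
    """Trait z-scores against the generating (truncated) per-sex distribution,
    so a 'per SD of trait' effect slope refers to the SD actually realized."""
    config = config or DEFAULT_COVARIATES
    sex = subject["sex"]
    out = {}
    for name, (mean, sd) in config[sex].items():
        if name in subject.index and sd > 0:
            lo, hi = COVARIATE_BOUNDS.get(name, (-np.inf, np.inf))
            m, s = _trait_moments(mean, sd, lo, hi)
            if s > 0:
                out[name] = (float(subject[name]) - m) / s
    return out


def _simulate_arrays(
    subject: pd.Series,
    schedule: pd.DataFrame,
    phase: str,
    effects: BiasEffectMap,
    noise: RTNoiseParams,
    rng: np.random.Generator,
    covariate_config: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Core RT generator; returns (rt_ms, response_side) arrays (NaN/None = missing)."""
    n = len(schedule)
    condition = schedule["condition"].to_numpy()
    duration = schedule["duration_ms"].to_numpy(float)
    probe = schedule["probe_side"].to_numpy()
    target = schedule["target_side"].to_numpy(object)

    trait_z = _trait_z(subject, covariate_config)
    sex = subject["sex"]
    shift = np.zeros(n)
    for cond in (COND_CSPLUS_NEUTRAL, COND_CSMINUS_NEUTRAL, COND_CSPLUS_CSMINUS):
        for dur in np.unique(duration):
            mask = (condition == cond) & (duration == dur)
            if not mask.any():
                continue
            e, d = effects.shifts(phase, cond, dur, sex, trait_z)
            congruent = probe[mask] == target[mask]
            shift[mask] = np.where(congruent, -e, -d)

    latent = float(subject["rt_base_ms"]) + noise.mu_ms + shift
    rt = rng.normal(latent, noise.sigma_ms, size=n)
    if noise.tau_ms > 0:
        rt += rng.exponential(noise.tau_ms, size=n)
    rt = np.clip(rt, 1.0, noise.max_response_ms)

    u = rng.random(n)
    premature = u < noise.premature_rate
    missing = (~premature) & (u < noise.premature_rate + noise.miss_rate)
    false = (~premature) & (~missing) & (
        u < noise.premature_rate + noise.miss_rate + noise.false_rate
    )
    rt[premature] = np.maximum(rng.uniform(0.0, 100.0, size=int(premature.sum())), 1e-3)
    rt[missing] = np.nan
    other = np.where(probe == "left", "right", "left")
    response = np.where(false, other, probe).astype(object)
    response[missing] = None
    return rt, response


def simulate_dotprobe_run(
    subject: pd.Series,
    schedule: pd.DataFrame,
    phase: str,
    effects: BiasEffectMap,
    noise: RTNoiseParams | None = None,
    seed: int = 0,
    covariate_config: dict | None = None,
) -> pd.DataFrame:
    """Simulate one subject's dot-probe run; returns tidy trial records."""
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    noise = noise or RTNoiseParams()
    rng = np.random.default_rng(seed)
    rt, response = _simulate_arrays(subject, schedule, phase, effects, noise, rng, covariate_config)
    out = schedule.copy()
    out.insert(0, "phase", phase)
    out.insert(0, "sex", subject["sex"])
    out.insert(0, "subject_id", subject["subject_id"])
    out["response_side"] = response
    out["rt_ms"] = rt
    return out[TRIAL_COLUMNS]


def simulate_experiment(
    subjects: pd.DataFrame,
    schedule: pd.DataFrame,
    effects: BiasEffectMap,
    noise: RTNoiseParams | None = None,
    phases: tuple[str, ...] = PHASES,
    seed: int = 0,
    covariate_config: dict | None = None,
) -> pd.DataFrame:
    """Simulate all subjects x phases on a common schedule (one tidy frame).

    A single generator is consumed in a fixed subject-major, phase-minor call
    order, so identical seeds yield identical frames.
    """
    noise = noise or RTNoiseParams()
    rng = np.random.default_rng(seed)
    n = len(schedule)
    rts, responses, sub_ids, sexes, phase_col = [], [], [], [], []
    for _, subject in subjects.iterrows():
        for phase in phases:
            rt, resp = _simulate_arrays(subject, schedule, phase, effects, noise, rng, covariate_config)
            rts.append(rt)
            responses.append(resp)
            sub_ids.append(np.full(n, subject["subject_id"], dtype=object))
            sexes.append(np.full(n, subject["sex"], dtype=object))
            phase_col.append(np.full(n, phase, dtype=object))
    reps = len(rts)
    base = pd.concat([schedule] * reps, ignore_index=True)
    base.insert(0, "phase", np.concatenate(phase_col))
    base.insert(0, "sex", np.concatenate(sexes))
    base.insert(0, "subject_id", np.concatenate(sub_ids))
    base["response_side"] = np.concatenate(responses)
    base["rt_ms"] = np.concatenate(rts)
    return base[TRIAL_COLUMNS]


def simulate_ratings(
    subjects: pd.DataFrame,
    params: RatingEffectParams | None = None,
    times: tuple[str, ...] = ("baseline", "post_conditioning", "post_test"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate VAS valence ratings per cue x time and post-conditioning
    CS-US contingency ratings. Returns (valence, contingency) frames."""
    allowed = {"baseline", "post_conditioning", "post_test"}
    if not set(times) <= allowed:
        raise ValueError(f"times must be a subset of {sorted(allowed)}")
    params = params or RatingEffectParams()
    rng = np.random.default_rng(seed)
    shift_by_cue = {CS_PLUS: params.csplus_valence_shift, CS_MINUS: params.csminus_valence_shift,
                    CS_NEUTRAL: 0.0}
    val_rows = []
    for _, subject in subjects.iterrows():
        for time in times:
            for cue in (CS_PLUS, CS_MINUS, CS_NEUTRAL):
                center = 0.0 if time == "baseline" else shift_by_cue[cue]
                value = center + (rng.normal(0.0, params.rating_noise_sd)
                                  if params.rating_noise_sd > 0 else 0.0)
                val_rows.append((subject["subject_id"], subject["sex"], time, cue,
                                 float(np.clip(value, -100, 100))))
    valence = pd.DataFrame(val_rows, columns=["subject_id", "sex", "time", "cue", "valence"])

    cont_rows = []
    for _, subject in subjects.iterrows():
        for cue in (CS_PLUS, CS_MINUS):
            key = (subject["sex"], cue)
            mean = params.contingency_means[key]
            sd = params.contingency_sds[key]
            value = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            cont_rows.append((subject["subject_id"], subject["sex"], cue,
                              float(np.clip(value, 0, 100))))
    contingency = pd.DataFrame(cont_rows, columns=["subject_id", "sex", "cue", "contingency_pct"])
    return valence, contingency


def index_change_noise_sd(
    noise: RTNoiseParams | None = None,
    trials_per_condition: int = 80,
    n_durations: int = 2,
    index: str = "avoidance",
) -> float:
    """Analytic trial-sampling SD of a baseline-to-test index change score.

    Each congruency arm holds ``trials_per_condition / (2 * n_durations)``
    trials; per-duration index variance follows from the ex-Gaussian trial
    variance, is divided by ``n_durations`` when durations are averaged, and
    doubled for the test-minus-baseline difference. For the engagement and
    disengagement indices the neutral arm (shared 40-trial condition, i.e.
    ``trials_per_condition / 2`` per duration at the default design) replaces
    one congruency arm.
    """
    noise = noise or RTNoiseParams()
    n_arm = trials_per_condition / (2 * n_durations)
    if index == "avoidance":
        var_dur = noise.rt_var * (2.0 / n_arm)
    elif index in ("engagement", "disengagement"):
        n_neutral = trials_per_condition / 2 / n_durations  # 40-trial neutral condition
        var_dur = noise.rt_var * (1.0 / n_arm + 1.0 / n_neutral)
    else:
        raise ValueError(f"unknown index {index!r}")
    return float(np.sqrt(2.0 * var_dur / n_durations))


def trait_slope_for_interaction_beta(beta: float, noise_sd: float) -> float:
    """Ms-per-trait-SD slope b such that the generating model
    ``y = b * sex * z(trait) + e`` (sex coded 0/1, balanced sexes) has a
    standardized sex x trait interaction coefficient of ``beta``.

    From Var(sex*z) = 1/2 and Var(y) = b^2/2 + s^2:
    ``b = s * beta * sqrt(2 / (1 - beta^2))``.
    """
    if not 0 <= beta < 1:
        raise ValueError("beta must lie in [0, 1)")
    return float(noise_sd * beta * np.sqrt(2.0 / (1.0 - beta**2)))
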