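"""Noncentral-F power analysis for the between-groups effect of a
repeated-measures design (the G*Power "ANOVA: repeated measures,
between factors" calculation).

For g groups, m repeated measurements, total N, Cohen's f, assumed
correlation rho among the repeated measures and nonsphericity epsilon, the
between-groups F test has df = (g - 1, N - g) and noncentrality

    lambda = f^2 * N * m * epsilon / (1 + (m - 1) * rho)

power = P(F'(df1, df2, lambda) > F_crit(alpha, df1, df2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the repeated-measures between-groups power test."""

    effect_size_f: float = 0.338
    alpha: float = 0.05
    target_power: float = 0.95
    n_groups: int = 2
    n_measurements: int = 8
    rho: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_size_f < 0:
            raise ValueError("effect_size_f must be >= 0")
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must lie in (0, 1)")
        if self.n_groups < 2 or self.n_measurements < 1:
            raise ValueError("need >= 2 groups and >= 1 measurement")
        m = self.n_measurements
        if not (-1.0 / max(m - 1, 1)) < self.rho < 1.0:
            raise ValueError("rho outside the positive-definite range")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")


def f_from_d(d: float) -> float:
    """Cohen's f from Cohen's d under the two-group convention, f = d / 2."""
    if d < 0:
        raise ValueError("d must be >= 0")
    return d / 2.0


def critical_f(alpha: float, df1: float, df2: float) -> float:
    """(1 - alpha) quantile of the central F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.isf(alpha, df1, df2))


def noncentrality(spec: PowerSpec, n_total: int) -> float:
    """Noncentrality parameter lambda for the between-groups effect."""
    m = spec.n_measurements
    return spec.effect_size_f**2 * n_total * m * spec.epsilon / (1.0 + (m - 1) * spec.rho)


def rm_between_power(spec: PowerSpec, n_total: int) -> float:
    """Achieved power of the between-groups test at total sample size N."""
    if n_total <= spec.n_groups:
        raise ValueError("N must exceed the number of groups")
    df1 = spec.n_groups - 1
    df2 = n_total - spec.n_groups
    lam = noncentrality(spec, n_total)
    crit = critical_f(spec.alpha, df1, df2)
    if lam == 0:
        return spec.alpha
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, max_n: int = 100_000) -> int:
    """Smallest total N, balanced over groups (N divisible by n_groups),
    with power >= target_power."""
    if spec.effect_size_f == 0:
        raise ValueError("power is unreachable at f = 0")
    g = spec.n_groups
    n = 2 * g  # smallest balanced N with df2 >= 1
    while n <= max_n:
        if rm_between_power(spec, n) >= spec.target_power:
            return n
        n += g
    raise ValueError(f"target power not reached by N = {max_n}")
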