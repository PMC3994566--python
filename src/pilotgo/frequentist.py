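"""Frequentist inference on the mean difference between two trial arms.

Pilot trials are rarely powered for the conventional 5% significance level,
so instead of a single 95% confidence interval this module produces a
*ladder* of intervals at several confidence levels and classifies each one
against the minimum clinically important difference (MCID). An interval that
contains both zero and the MCID is equivocal: the data preclude neither "no
effect" nor "clinically meaningful effect".

All inference runs from per-arm sufficient statistics (n, mean, SD), so the
printed cells of a published table are enough to reproduce its analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
from scipy import stats

from .trial_data import TwoArmTrial

__all__ = [
    "EffectEstimate",
    "Interval",
    "DecisionCategory",
    "VarianceRule",
    "effect_estimate",
    "confidence_interval",
    "p_value",
    "one_sided_p_value",
    "ci_ladder",
    "classify_interval",
    "power_two_sample",
    "DEFAULT_LADDER_LEVELS",
]

#: Default ladder: 50% to 95% in steps of 5 percentage points.
DEFAULT_LADDER_LEVELS = tuple(float(x) for x in np.round(np.arange(0.50, 0.951, 0.05), 2))


class VarianceRule(str, enum.Enum):
    POOLED = "pooled"
    WELCH = "welch"


@dataclass(frozen=True)
class EffectEstimate:
    """Estimated mean difference (intervention minus control) with its SE.

    ``df`` is n1 + n2 - 2 under the pooled-variance rule, or the
    Welch-Satterthwaite value under unequal variances. The arm sizes are kept
    so that the allocation ratio r = n1/n2 is recoverable: for arm sizes
    (n1, n2) the pooled SE equals s_p * sqrt((r+1)/(r*n)) with n = n2.
    """

    d: float
    se: float
    df: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.d):
            raise ValueError("effect estimate d must be finite")
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"standard error must be positive, got {self.se}")
        if self.df <= 0:
            raise ValueError(f"degrees of freedom must be positive, got {self.df}")


@dataclass(frozen=True)
class Interval:
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"confidence level must be in (0, 1), got {self.level}")
        if self.lower > self.upper:
            raise ValueError(f"interval has lower {self.lower} > upper {self.upper}")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


class DecisionCategory(enum.Enum):
    """Classification of a confidence interval against zero and the MCID."""

    MEETS_MCID = "meets_mcid"
    POSITIVE_UNCLEAR = "positive_unclear"
    EQUIVOCAL = "equivocal"
    NO_MEANINGFUL_BENEFIT = "no_meaningful_benefit"
    HARMFUL = "harmful"


def effect_estimate(
    trial: TwoArmTrial,
    variance_rule: VarianceRule | str = VarianceRule.POOLED,
) -> EffectEstimate:
    """Two-sample mean difference with its standard error and t degrees of freedom.

    Under the default pooled rule the variance is
    s_p^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2) and the SE is
    s_p * sqrt(1/n1 + 1/n2) on n1 + n2 - 2 degrees of freedom. The Welch
    option drops the equal-variance assumption and uses Satterthwaite
    degrees of freedom.
    """
    variance_rule = VarianceRule(variance_rule)
    a, b = trial.intervention, trial.control
    if a.n < 2 or b.n < 2:
        raise ValueError("inference requires n >= 2 in each arm")
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both arms have zero SD: the t statistic is degenerate")
    d = a.mean - b.mean
    if variance_rule is VarianceRule.POOLED:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df: float = a.n + b.n - 2
    else:
        v1, v2 = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (a.n - 1) + v2**2 / (b.n - 1))
    return EffectEstimate(d=d, se=se, df=df, n1=a.n, n2=b.n)


def confidence_interval(effect: EffectEstimate, level: float) -> Interval:
    """Central t confidence interval d +/- t_{df,(1+level)/2} * se."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    half = float(stats.t.ppf((1 + level) / 2, effect.df)) * effect.se
    return Interval(lower=float(effect.d - half), upper=float(effect.d + half), level=float(level))


def p_value(effect: EffectEstimate) -> float:
    """Two-sided p-value for the null of no mean difference."""
    return float(2 * stats.t.sf(abs(effect.d) / effect.se, effect.df))


def one_sided_p_value(effect: EffectEstimate) -> float:
    """One-sided p-value for benefit (positive difference favourable)."""
    return float(stats.t.sf(effect.d / effect.se, effect.df))


def ci_ladder(
    effect: EffectEstimate,
    levels: Sequence[float] = DEFAULT_LADDER_LEVELS,
) -> List[Interval]:
    """Nested confidence intervals at strictly increasing levels."""
    levels = list(levels)
    if not levels:
        raise ValueError("at least one confidence level is required")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError(f"levels must be strictly increasing, got {levels}")
    return [confidence_interval(effect, level) for level in levels]


def classify_interval(interval: Interval, mcid: float) -> DecisionCategory:
    """Classify one interval against zero and a positive MCID.

    The five categories partition all intervals. "At or above the MCID"
    counts as meeting it, so ties at the MCID boundary favour the stronger
    category.
    """
    if mcid <= 0:
        raise ValueError(f"mcid must be positive, got {mcid}")
    if interval.upper < 0:
        return DecisionCategory.HARMFUL
    if interval.lower >= mcid:
        return DecisionCategory.MEETS_MCID
    if interval.upper < mcid:
        return DecisionCategory.NO_MEANINGFUL_BENEFIT
    if interval.lower > 0:
        return DecisionCategory.POSITIVE_UNCLEAR
    return DecisionCategory.EQUIVOCAL


def power_two_sample(
    delta: float,
    sd: float,
    n_per_arm: int,
    alpha: float = 0.05,
    sides: int = 1,
) -> float:
    """Normal-approximation power to detect a mean difference ``delta``.

    Power = Phi(delta / (sd * sqrt(2/n)) - z_{1-alpha}) for a one-sided test
    (z_{1-alpha/2} for two-sided, ignoring the negligible wrong-tail mass).
    Used at the design stage; pilot trials typically land far below the
    conventional 80%.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be positive")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sides not in (1, 2):
        raise ValueError(f"sides must be 1 or 2, got {sides}")
    z_crit = stats.norm.ppf(1 - alpha / sides)
    ncp = delta / (sd * math.sqrt(2 / n_per_arm))
    return float(stats.norm.cdf(ncp - z_crit))
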