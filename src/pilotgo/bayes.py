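"""Conjugate-Normal Bayesian Go/No-Go analysis of a pilot effect estimate.

The treatment effect theta (mean difference, intervention minus control)
gets a Normal prior; the observed pilot difference d with standard error se
is treated as a Normal likelihood with known variance. The posterior is
again Normal, obtained by precision weighting:

    1/s_post^2 = 1/s_prior^2 + 1/se^2
    d_post     = s_post^2 * (d_prior / s_prior^2 + d / se^2)

A non-informative prior carries zero precision, so the posterior equals the
observed-data distribution exactly. The Go/No-Go verdict asks whether
P(theta > MCID | data) clears a pre-set hurdle such as 75%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .frequentist import EffectEstimate

__all__ = [
    "NormalPrior",
    "Posterior",
    "GoCriterion",
    "GoDecision",
    "DensityTriplet",
    "elicit_prior",
    "posterior_update",
    "prob_exceeds",
    "go_no_go",
    "density_triplet",
]


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior on the mean difference; ``sd = inf`` is the non-informative sentinel."""

    mean: float
    sd: float
    label: str = "prior"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"prior sd must be positive (or inf), got {self.sd}")
        if math.isfinite(self.sd) and not math.isfinite(self.mean):
            raise ValueError("prior mean must be finite for an informative prior")

    @classmethod
    def noninformative(cls, label: str = "non-informative") -> "NormalPrior":
        return cls(mean=0.0, sd=math.inf, label=label)

    @property
    def is_noninformative(self) -> bool:
        return math.isinf(self.sd)

    @property
    def precision(self) -> float:
        return 0.0 if self.is_noninformative else 1.0 / self.sd**2


@dataclass(frozen=True)
class Posterior:
    """Normal posterior for the mean difference theta."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"posterior sd must be positive and finite, got {self.sd}")
        if not math.isfinite(self.mean):
            raise ValueError("posterior mean must be finite")

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval from normal quantiles."""
        half = stats.norm.ppf((1 + level) / 2) * self.sd
        return (self.mean - half, self.mean + half)


@dataclass(frozen=True)
class GoCriterion:
    """Require P(theta > threshold_difference) > required_probability to go."""

    threshold_difference: float
    required_probability: float

    def __post_init__(self) -> None:
        if not 0 < self.required_probability < 1:
            raise ValueError(
                f"required_probability must be in (0, 1), got {self.required_probability}"
            )


@dataclass(frozen=True)
class GoDecision:
    probability: float
    go: bool
    criterion: GoCriterion


def elicit_prior(
    mean: float,
    lower: float,
    upper: float,
    coverage: float = 0.90,
    label: str = "elicited",
) -> NormalPrior:
    """Build a Normal prior from its mean and a symmetric central interval.

    An expert statement like "mean difference 4, 90% certain it lies between
    -1 and 9" maps to sd = (upper - lower) / (2 z_{(1+coverage)/2}) with the
    exact standard-normal quantile. The interval must be centred on the mean
    (tolerance 1e-6); an asymmetric interval is rejected rather than
    silently recentred, because it is not expressible as a Normal central
    interval.
    """
    if not lower < upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    midpoint = (lower + upper) / 2
    if abs(mean - midpoint) > 1e-6:
        raise ValueError(
            f"interval ({lower}, {upper}) is not centred on mean {mean} "
            f"(midpoint {midpoint}); a Normal central interval must be symmetric"
        )
    z = stats.norm.ppf((1 + coverage) / 2)
    return NormalPrior(mean=mean, sd=(upper - lower) / (2 * z), label=label)


def posterior_update(prior: NormalPrior, effect: EffectEstimate) -> Posterior:
    """Conjugate update of a Normal prior with the observed effect estimate.

    The observed difference contributes precision 1/se^2; for arm sizes
    (n1, n2) = (r n, n) this is r n / (s_pilot^2 (r + 1)) in allocation-ratio
    form. With the non-informative sentinel the posterior equals the
    observed N(d, se^2) exactly.
    """
    p_obs = 1.0 / effect.se**2
    p_pri = prior.precision
    var_post = 1.0 / (p_obs + p_pri)
    mean_post = var_post * (effect.d * p_obs + (prior.mean * p_pri if p_pri > 0 else 0.0))
    return Posterior(mean=mean_post, sd=math.sqrt(var_post))


def prob_exceeds(posterior: Posterior, d_i: float) -> float:
    """P(theta > d_i | data) = Phi((d_post - d_i) / s_post)."""
    return float(stats.norm.cdf((posterior.mean - d_i) / posterior.sd))


def go_no_go(posterior: Posterior, criterion: GoCriterion) -> GoDecision:
    """Go when the exceedance probability strictly clears the hurdle."""
    prob = prob_exceeds(posterior, criterion.threshold_difference)
    return GoDecision(probability=prob, go=prob > criterion.required_probability, criterion=criterion)


@dataclass(frozen=True)
class DensityTriplet:
    """Prior, observed, and posterior Normal densities on a shared grid.

    ``prior_density`` is ``None`` for a non-informative prior (an improper
    flat density has no curve to draw).
    """

    grid: np.ndarray
    prior_density: Optional[np.ndarray]
    observed_density: np.ndarray
    posterior_density: np.ndarray
    label: str = ""


def density_triplet(
    prior: NormalPrior,
    effect: EffectEstimate,
    posterior: Posterior,
    grid: Optional[np.ndarray] = None,
    n_points: int = 512,
    pad_sds: float = 4.0,
) -> DensityTriplet:
    """Evaluate the three densities for plotting.

    The default grid spans all component means padded by ``pad_sds`` times
    the widest finite SD, with 512 points.
    """
    if grid is None:
        sds = [effect.se, posterior.sd] + ([] if prior.is_noninformative else [prior.sd])
        means = [effect.d, posterior.mean] + ([] if prior.is_noninformative else [prior.mean])
        pad = pad_sds * max(sds)
        grid = np.linspace(min(means) - pad, max(means) + pad, n_points)
    else:
        grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or not np.all(np.isfinite(grid)):
        raise ValueError("grid must have at least 2 finite points")
    prior_density = (
        None if prior.is_noninformative else stats.norm.pdf(grid, prior.mean, prior.sd)
    )
    return DensityTriplet(
        grid=grid,
        prior_density=prior_density,
        observed_density=stats.norm.pdf(grid, effect.d, effect.se),
        posterior_density=stats.norm.pdf(grid, posterior.mean, posterior.sd),
        label=prior.label,
    )
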