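"""Pipeline orchestration, JSON reports, and the two figure renderers.

The report mirrors how pilot-trial results are tabulated: an effect block
(difference, SE, p-values), a confidence-interval ladder with each interval
classified against the MCID, and a Bayesian block with one row per prior
(posterior mean, posterior SD, exceedance probability, go verdict). Numbers
appear at full precision and at display rounding (differences and bounds to
1 dp, p-values to 3 dp, probabilities to 2 dp).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .bayes import (
    DensityTriplet,
    GoCriterion,
    NormalPrior,
    density_triplet,
    elicit_prior,
    go_no_go,
    posterior_update,
)
from .frequentist import (
    DEFAULT_LADDER_LEVELS,
    Interval,
    VarianceRule,
    ci_ladder,
    classify_interval,
    effect_estimate,
    one_sided_p_value,
    p_value,
)
from .trial_data import (
    TwoArmTrial,
    load_config,
    read_summary_config,
    read_trial_csv,
    summarize_arm,
)

__all__ = ["AnalysisConfig", "Report", "run_pipeline", "render_ladder", "render_densities"]


def _prior_from_mapping(entry: dict) -> NormalPrior:
    label = str(entry.get("label", "prior"))
    if entry.get("noninformative"):
        return NormalPrior.noninformative(label=label)
    for key in ("mean", "lower", "upper"):
        if key not in entry:
            raise ValueError(f"prior {label!r} is missing field {key!r}")
    return elicit_prior(
        float(entry["mean"]),
        float(entry["lower"]),
        float(entry["upper"]),
        float(entry.get("coverage", 0.90)),
        label=label,
    )


@dataclass
class AnalysisConfig:
    """Validated inputs for one analysis run.

    Exactly one of ``csv_path`` and ``trial`` must be supplied.
    """

    mcid: float
    csv_path: Optional[Union[str, Path]] = None
    trial: Optional[TwoArmTrial] = None
    levels: Sequence[float] = DEFAULT_LADDER_LEVELS
    variance_rule: Union[str, VarianceRule] = VarianceRule.POOLED
    priors: Sequence[NormalPrior] = field(default_factory=list)
    go_threshold: float = 0.75
    seed: int = 0
    report_path: Optional[Union[str, Path]] = None
    ladder_plot: Optional[Union[str, Path]] = None
    density_plot: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        if (self.csv_path is None) == (self.trial is None):
            raise ValueError("exactly one input source (csv_path or trial) is required")
        if self.mcid <= 0:
            raise ValueError(f"mcid must be positive, got {self.mcid}")
        if not 0 < self.go_threshold < 1:
            raise ValueError(f"go_threshold must be in (0, 1), got {self.go_threshold}")
        self.variance_rule = VarianceRule(self.variance_rule)

    @classmethod
    def from_file(cls, path: Union[str, Path], **overrides) -> "AnalysisConfig":
        """Build a config from a JSON/YAML file; keyword overrides win."""
        data = load_config(path)
        kwargs: dict = {}
        if "csv" in data:
            kwargs["csv_path"] = data["csv"]
        elif "intervention" in data:
            kwargs["trial"] = read_summary_config(path)
        if "mcid" in data:
            kwargs["mcid"] = float(data["mcid"])
        if "levels" in data:
            kwargs["levels"] = [float(x) for x in data["levels"]]
        if "variance_rule" in data:
            kwargs["variance_rule"] = data["variance_rule"]
        if "priors" in data:
            kwargs["priors"] = [_prior_from_mapping(p) for p in data["priors"]]
        if "go_threshold" in data:
            kwargs["go_threshold"] = float(data["go_threshold"])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        kwargs.update(overrides)
        return cls(**kwargs)

    def fingerprint(self) -> str:
        """Stable hash of the analysis inputs, for report provenance."""
        payload = {
            "csv_path": str(self.csv_path) if self.csv_path else None,
            "trial": None
            if self.trial is None
            else {
                "intervention": vars(self.trial.intervention),
                "control": vars(self.trial.control),
                "outcome_name": self.trial.outcome_name,
                "n_randomised_total": self.trial.n_randomised_total,
            },
            "mcid": self.mcid,
            "levels": list(self.levels),
            "variance_rule": self.variance_rule.value,
            "priors": [
                {"label": p.label, "mean": p.mean, "sd": None if p.is_noninformative else p.sd}
                for p in self.priors
            ],
            "go_threshold": self.go_threshold,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Report:
    """Serializable analysis result; ``to_json``/``from_json`` round-trip losslessly."""

    payload: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.payload, sort_keys=True, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        return cls(payload=json.loads(text))

    def __getitem__(self, key: str):
        return self.payload[key]


def _round(x: float, dp: int) -> float:
    return float(round(x, dp))


def run_pipeline(config: AnalysisConfig) -> Report:
    """Run the full analysis: data -> effect -> ladder -> Bayesian block.

    Writes the JSON report and any requested plots, then returns the Report.
    """
    if config.csv_path is not None:
        arm_a, arm_b = read_trial_csv(config.csv_path)
        n_randomised = arm_a.n_randomised + arm_b.n_randomised
        trial = TwoArmTrial(
            intervention=summarize_arm(arm_a),
            control=summarize_arm(arm_b),
            n_randomised_total=n_randomised,
        )
    else:
        trial = config.trial
    assert trial is not None

    effect = effect_estimate(trial, config.variance_rule)
    ladder = ci_ladder(effect, list(config.levels))
    p2, p1 = p_value(effect), one_sided_p_value(effect)

    ladder_block = [
        {
            "level": iv.level,
            "lower": iv.lower,
            "upper": iv.upper,
            "category": classify_interval(iv, config.mcid).value,
            "display": {"lower": _round(iv.lower, 1), "upper": _round(iv.upper, 1)},
        }
        for iv in ladder
    ]

    bayes_block = []
    triplets: List[DensityTriplet] = []
    criterion = GoCriterion(
        threshold_difference=config.mcid, required_probability=config.go_threshold
    )
    for prior in config.priors:
        post = posterior_update(prior, effect)
        decision = go_no_go(post, criterion)
        triplets.append(density_triplet(prior, effect, post))
        bayes_block.append(
            {
                "prior": {
                    "label": prior.label,
                    "mean": None if prior.is_noninformative else prior.mean,
                    "sd": None if prior.is_noninformative else prior.sd,
                    "noninformative": prior.is_noninformative,
                },
                "posterior_mean": post.mean,
                "posterior_sd": post.sd,
                "prob_exceeds_mcid": decision.probability,
                "go": decision.go,
                "display": {
                    "posterior_mean": _round(post.mean, 1),
                    "posterior_sd": _round(post.sd, 1),
                    "prob_exceeds_mcid": _round(decision.probability, 2),
                },
            }
        )

    payload = {
        "outcome_name": trial.outcome_name,
        "arms": {
            "intervention": vars(trial.intervention),
            "control": vars(trial.control),
        },
        "attrition_rate": trial.attrition(),
        "effect": {
            "d": effect.d,
            "se": effect.se,
            "df": effect.df,
            "n1": effect.n1,
            "n2": effect.n2,
            "p_two_sided": p2,
            "p_one_sided": p1,
            "display": {"d": _round(effect.d, 1), "p_two_sided": _round(p2, 3)},
        },
        "mcid": config.mcid,
        "ladder": ladder_block,
        "bayes": bayes_block,
        "go_threshold": config.go_threshold,
        "provenance": {
            "tool": "pilotgo",
            "version": __version__,
            "config_hash": config.fingerprint(),
            "seed": config.seed,
        },
    }
    report = Report(payload=payload)

    if config.report_path is not None:
        Path(config.report_path).write_text(report.to_json() + "\n")
    if config.ladder_plot is not None:
        intervals = [Interval(b["lower"], b["upper"], b["level"]) for b in ladder_block]
        render_ladder(intervals, config.mcid, config.ladder_plot, point=effect.d)
    if config.density_plot is not None and triplets:
        render_densities(triplets, config.density_plot, mcid=config.mcid)
    return report


def render_ladder(
    ladder: Sequence[Interval],
    mcid: float,
    path: Union[str, Path],
    point: Optional[float] = None,
) -> Path:
    """Draw the CI ladder: one horizontal interval per level, lines at 0 and the MCID."""
    if not ladder:
        raise ValueError("ladder is empty")
    fig, ax = plt.subplots(figsize=(6, 0.5 + 0.4 * len(ladder)))
    for i, iv in enumerate(ladder):
        ax.plot([iv.lower, iv.upper], [i, i], lw=2, color="C0", solid_capstyle="butt")
        if point is not None:
            ax.plot([point], [i], "o", color="C0", ms=4)
    ax.axvline(0.0, color="black", lw=1)
    ax.axvline(mcid, color="C3", lw=1, ls="--", label=f"MCID = {mcid:g}")
    ax.set_yticks(range(len(ladder)))
    ax.set_yticklabels([f"{iv.level:.0%}" for iv in ladder])
    ax.set_xlabel("mean difference")
    ax.set_ylabel("confidence level")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def render_densities(
    triplets: Sequence[DensityTriplet],
    path: Union[str, Path],
    mcid: Optional[float] = None,
) -> Path:
    """Draw prior/observed/posterior densities, one panel per prior."""
    if not triplets:
        raise ValueError("no density triplets to draw")
    fig, axes = plt.subplots(
        len(triplets), 1, figsize=(6, 2.4 * len(triplets)), sharex=True, squeeze=False
    )
    for ax, trip in zip(axes.ravel(), triplets):
        if trip.prior_density is not None:
            ax.plot(trip.grid, trip.prior_density, ls=":", color="C2", label="prior")
        ax.plot(trip.grid, trip.observed_density, ls="--", color="C0", label="observed")
        ax.plot(trip.grid, trip.posterior_density, ls="-", color="C1", label="posterior")
        if mcid is not None:
            ax.axvline(mcid, color="C3", lw=1, ls="--")
        ax.set_title(trip.label, fontsize=10)
        ax.legend(frameon=False, fontsize=8)
    axes.ravel()[-1].set_xlabel("mean difference")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
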