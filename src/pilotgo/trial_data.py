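"""Data model for two-arm continuous-outcome trials.

Raw participant-level outcomes are reduced to per-arm sufficient statistics
(n, mean, sample SD) by complete-case analysis: missing outcomes are dropped,
never imputed. Attrition is accounted for separately so that the dropout rate
can be reported alongside the effect estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArmSummary",
    "TwoArmTrial",
    "RawArm",
    "summarize_arm",
    "attrition_rate",
    "read_trial_csv",
    "read_summary_config",
]

#: Accepted missing-value tokens in participant CSV files.
MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class ArmSummary:
    """Sufficient statistics for one trial arm: complete-case n, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"arm {self.label!r}: n must be >= 1, got {self.n}")
        if not math.isfinite(self.mean):
            raise ValueError(f"arm {self.label!r}: mean must be finite")
        if not math.isfinite(self.sd) or self.sd < 0:
            raise ValueError(f"arm {self.label!r}: sd must be finite and >= 0, got {self.sd}")


@dataclass(frozen=True)
class TwoArmTrial:
    """A two-arm parallel trial summarised per arm.

    ``n_randomised_total``, when known, allows the attrition rate to be
    reported (randomised minus analysed, over randomised).
    """

    intervention: ArmSummary
    control: ArmSummary
    outcome_name: str = "outcome"
    n_randomised_total: Optional[int] = None

    def __post_init__(self) -> None:
        n_obs = self.intervention.n + self.control.n
        if self.n_randomised_total is not None and self.n_randomised_total < n_obs:
            raise ValueError(
                f"n_randomised_total={self.n_randomised_total} is below the "
                f"{n_obs} observed participants"
            )

    @property
    def n_observed(self) -> int:
        return self.intervention.n + self.control.n

    def attrition(self) -> Optional[float]:
        """Attrition rate if the randomised total is known, else ``None``."""
        if self.n_randomised_total is None:
            return None
        return attrition_rate(self.n_randomised_total, self.n_observed)


@dataclass(frozen=True)
class RawArm:
    """Participant-level outcomes for one arm; ``None`` marks a missing outcome."""

    label: str
    outcomes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.outcomes) == 0:
            raise ValueError(f"arm {self.label!r}: outcome list is empty")
        object.__setattr__(self, "outcomes", tuple(self.outcomes))

    @property
    def n_missing(self) -> int:
        return sum(1 for v in self.outcomes if _is_missing(v))

    @property
    def n_randomised(self) -> int:
        return len(self.outcomes)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def summarize_arm(raw: RawArm) -> ArmSummary:
    """Reduce raw outcomes to complete-case sufficient statistics.

    Missing values are excluded; the SD uses the n-1 denominator and is 0.0
    for a single observation.

    Raises
    ------
    ValueError
        If every outcome in the arm is missing.
    """
    values = np.asarray([v for v in raw.outcomes if not _is_missing(v)], dtype=float)
    if values.size == 0:
        raise ValueError(f"arm {raw.label!r}: all outcomes are missing")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return ArmSummary(label=raw.label, n=int(values.size), mean=float(np.mean(values)), sd=sd)


def attrition_rate(n_randomised: int, n_observed: int) -> float:
    """Fraction of randomised participants without an observed outcome."""
    if n_randomised < 1:
        raise ValueError("n_randomised must be positive")
    if n_observed < 0 or n_observed > n_randomised:
        raise ValueError(
            f"n_observed={n_observed} must lie in [0, n_randomised={n_randomised}]"
        )
    return (n_randomised - n_observed) / n_randomised


def _parse_outcome(token, row: int):
    if token is None:
        return None
    text = str(token).strip()
    if text in MISSING_TOKENS or (isinstance(token, float) and math.isnan(token)):
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"row {row}: outcome {text!r} is neither numeric nor a missing "
            f"marker (empty or 'NA')"
        ) from None


def read_trial_csv(path: Union[str, Path]) -> tuple[RawArm, RawArm]:
    """Read a participant CSV with columns participant_id, group, outcome.

    The group column must contain exactly two distinct labels. The outcome is
    numeric, empty, or the literal token ``NA``; anything else is a parse
    error rather than silently treated as missing. Arms are returned in order
    of first appearance (first-seen group is taken as the intervention arm by
    downstream callers unless told otherwise).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"participant_id", "group", "outcome"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"CSV is missing required columns: {sorted(missing_cols)}")
    labels = list(dict.fromkeys(frame["group"]))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, found {len(labels)}: {labels}")
    arms = []
    for label in labels:
        rows = frame.index[frame["group"] == label]
        outcomes = [_parse_outcome(frame.at[i, "outcome"], int(i) + 2) for i in rows]
        arms.append(RawArm(label=label, outcomes=tuple(outcomes)))
    return arms[0], arms[1]


def _arm_from_mapping(entry: dict, role: str) -> ArmSummary:
    for key in ("label", "n", "mean", "sd"):
        if key not in entry:
            raise ValueError(f"{role} arm summary is missing field {key!r}")
    return ArmSummary(
        label=str(entry["label"]),
        n=int(entry["n"]),
        mean=float(entry["mean"]),
        sd=float(entry["sd"]),
    )


def read_summary_config(path: Union[str, Path]) -> TwoArmTrial:
    """Read per-arm summary statistics from a JSON or YAML config file.

    Expected shape::

        intervention: {label: clinic, n: 17, mean: 68.0, sd: 17.6}
        control:      {label: home,   n: 14, mean: 55.1, sd: 19.8}
        outcome_name: "SF-36 GH score"       # optional
        n_randomised_total: 40               # optional
    """
    data = load_config(path)
    for role in ("intervention", "control"):
        if role not in data:
            raise ValueError(f"summary config is missing the {role!r} arm")
    kwargs = {}
    if "outcome_name" in data:
        kwargs["outcome_name"] = str(data["outcome_name"])
    if data.get("n_randomised_total") is not None:
        kwargs["n_randomised_total"] = int(data["n_randomised_total"])
    return TwoArmTrial(
        intervention=_arm_from_mapping(data["intervention"], "intervention"),
        control=_arm_from_mapping(data["control"], "control"),
        **kwargs,
    )


def load_config(path: Union[str, Path]) -> dict:
    """Load a JSON or YAML mapping; the format is chosen by file suffix."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping at the top level")
    return data
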