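"""Built-in example: the leg-ulcer community-clinic trial, SF-36 General Health.

A randomised trial of community leg ulcer clinics (four-layer compression
bandaging) versus usual district-nurse care, with the SF-36 General Health
(GH) dimension score (0 poor to 100 good) measured at 3 and 12 months.
Treating the first 40 randomised patients' 3-month data as a notional pilot
gives a small two-arm dataset with 22.5% missingness; the 12-month data on
all 233 randomised patients plays the definitive-trial role. Only the
published per-arm summary statistics are stored here.
"""

from __future__ import annotations

from .bayes import NormalPrior, elicit_prior
from .trial_data import ArmSummary, TwoArmTrial

__all__ = [
    "leg_ulcer_pilot",
    "leg_ulcer_definitive",
    "leg_ulcer_priors",
    "MCID_SF36_GH",
]

#: Minimum clinically important difference used for the SF-36 GH score.
MCID_SF36_GH = 5.0


def leg_ulcer_pilot() -> TwoArmTrial:
    """3-month SF-36 GH summaries for the notional 40-patient pilot.

    31 of 40 had complete data (17 clinic, 14 home), i.e. 22.5% attrition.
    """
    return TwoArmTrial(
        intervention=ArmSummary(label="clinic", n=17, mean=68.0, sd=17.6),
        control=ArmSummary(label="home", n=14, mean=55.1, sd=19.8),
        outcome_name="SF-36 GH score (3 months)",
        n_randomised_total=40,
    )


def leg_ulcer_definitive() -> TwoArmTrial:
    """12-month SF-36 GH summaries for the full 233-patient trial (155 complete)."""
    return TwoArmTrial(
        intervention=ArmSummary(label="clinic", n=80, mean=56.0, sd=22.8),
        control=ArmSummary(label="home", n=75, mean=52.7, sd=23.9),
        outcome_name="SF-36 GH score (12 months)",
        n_randomised_total=233,
    )


def leg_ulcer_priors() -> list[NormalPrior]:
    """The three illustrative priors for the mean difference in GH score.

    Non-informative; pessimistic (mean 4, 90% central interval -1 to 9);
    optimistic (mean 7, 90% central interval 4 to 10).
    """
    return [
        NormalPrior.noninformative(),
        elicit_prior(4.0, -1.0, 9.0, 0.90, label="pessimistic"),
        elicit_prior(7.0, 4.0, 10.0, 0.90, label="optimistic"),
    ]
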