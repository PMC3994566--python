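# pilotgo

Tools for interpreting **pilot randomized trials** — small two-arm studies
run before a definitive trial, which are almost never powered for the
conventional 5% significance level. Instead of a lone p-value, `pilotgo`
frames the pilot evidence three ways:

1. **A confidence-interval ladder against the MCID.** The pooled-variance
   two-sample t effect estimate is shown at several confidence levels
   (default 50%–95%) and each interval is classified against zero and the
   *minimum clinically important difference* (MCID): an interval containing
   both 0 and the MCID is *equivocal*; one excluding 0 but crossing the
   MCID is *positive but unclear*; one wholly at or above the MCID *meets*
   it.
2. **A conjugate-Normal Bayesian Go/No-Go decision.** With a Normal prior
   θ ~ N(μ_prior, σ²_prior) on the mean difference and the observed
   difference d with standard error *se* treated as a known-variance Normal
   likelihood, the posterior follows by precision weighting:

   1/s²_post = 1/σ²_prior + 1/se²,  d_post = s²_post (μ_prior/σ²_prior + d/se²)

   The decision quantity is the exceedance probability
   P(θ > MCID | data) = Φ((d_post − MCID)/s_post), compared against a
   pre-set hurdle such as 75%. Priors are elicited from a mean and a
   symmetric central interval ("90% sure the difference is between −1 and
   9"); a non-informative prior (zero precision) makes the posterior equal
   the observed-data distribution exactly.
3. **Operating characteristics by simulation.** A seeded generator draws
   two Normal arms with missing-completely-at-random dropout and measures
   go-rates per criterion per true effect: the false-go (type-I) rate at
   δ = 0 and the true-go rate at δ = MCID, for relaxed one-sided thresholds
   (α = 0.2, 0.25 have been proposed for early-phase screening) and
   Bayesian hurdles alike.

Intended users: trial statisticians and methodologists deciding whether a
pilot justifies a definitive trial.

## Worked example

The built-in dataset is a leg-ulcer trial (community compression-bandaging
clinics vs usual home care) with the SF-36 General Health score (0–100,
MCID = 5 points). The 3-month data on the first 40 randomised patients
(31 complete) plays the pilot role; the 12-month data on all 233 (155
complete) is the definitive analysis. `pilotgo demo` prints:

```
== Pilot (3-month SF-36 GH) ==
difference 12.9  95% CI (-0.8, 26.6)  p = 0.065
   non-informative: posterior 12.9 (sd 6.7), P(>MCID) = 0.88, GO
       pessimistic: posterior 5.5 (sd 2.8), P(>MCID) = 0.57, NO-GO
        optimistic: posterior 7.4 (sd 1.8), P(>MCID) = 0.91, GO
== Definitive (12-month SF-36 GH) ==
difference 3.3  95% CI (-4.1, 10.7)  p = 0.380
   non-informative: posterior 3.3 (sd 3.8), P(>MCID) = 0.33, NO-GO
       pessimistic: posterior 3.7 (sd 2.4), P(>MCID) = 0.29, NO-GO
        optimistic: posterior 6.3 (sd 1.6), P(>MCID) = 0.78, GO
```

Reading the pilot block: the 12.9-point difference is significant at the
10% but not the 5% level, and the 95% CI is equivocal (contains 0 and 5),
yet 80%/90% intervals exclude 0 and the 75% interval lies wholly at or
above the MCID — preliminary evidence of a clinically meaningful effect.
Under a non-informative or optimistic prior the probability of exceeding
the MCID clears a 75% hurdle (go); a pessimistic prior pulls the small
pilot posterior below it (no-go), showing how strongly the prior can steer
a small study. The 12-month definitive analysis (difference 3.3, p = 0.380)
does not replicate the pilot's 3-month effect — a caution about surrogate
endpoints and relaxed pilot thresholds.

Library use mirrors the CLI:

```python
from pilotgo import (ArmSummary, TwoArmTrial, effect_estimate,
                     elicit_prior, posterior_update, prob_exceeds)

trial = TwoArmTrial(ArmSummary("clinic", 17, 68.0, 17.6),
                    ArmSummary("home", 14, 55.1, 19.8))
effect = effect_estimate(trial)                     # d=12.9, se=6.72, df=29
prior = elicit_prior(4, -1, 9, 0.90)                # pessimistic, sd=3.04
post = posterior_update(prior, effect)              # N(5.5, 2.77)
prob_exceeds(post, 5.0)                             # 0.573
```

Other subcommands: `pilotgo analyze` (CSV or summary-statistics input,
ladder plot), `pilotgo bayes` (repeatable `--prior`, density plot),
`pilotgo power`, and `pilotgo simulate` (scenario YAML → go-rate table).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged pilot arm summaries alone, the posterior
means and SDs and the MCID-exceedance probabilities under the
non-informative, pessimistic, and optimistic priors, and writes them as
JSON at the display precision used above.
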