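# Methods

## Statistical model

The outcome is a continuous score measured once per participant in a
two-arm parallel trial. Analysis is complete-case throughout: missing
outcomes are dropped, never imputed, and the attrition rate
(randomised − analysed)/randomised is reported alongside the estimate.
Per-arm sufficient statistics are (n, mean, sample SD with the n−1
denominator); everything downstream runs from these, so a published
summary table is a complete input.

### Frequentist inference

The effect is the mean difference d = mean₁ − mean₂ (intervention minus
control). Under the default **pooled** variance rule,

    s_p² = ((n₁−1)sd₁² + (n₂−1)sd₂²) / (n₁+n₂−2),
    se   = s_p √(1/n₁ + 1/n₂),   df = n₁ + n₂ − 2.

Writing r = n₁/n₂ and n = n₂, 1/n₁ + 1/n₂ = (r+1)/(rn), so the
allocation-ratio form of the standard error is recovered for any arm
sizes. A Welch option (Satterthwaite df) is available but the pooled rule
is the default because pilot analyses conventionally assume a common
variance. Confidence intervals use central t quantiles; p-values are
two-sided by default with a one-sided variant for directional go rules.

The **CI ladder** evaluates one effect at several levels (default 0.50 to
0.95 in steps of 0.05) and classifies each interval against 0 and the
MCID into five exhaustive, mutually exclusive categories: HARMFUL
(upper < 0), MEETS_MCID (lower ≥ MCID), NO_MEANINGFUL_BENEFIT
(0 ≤ upper < MCID), POSITIVE_UNCLEAR (lower > 0, interval crosses the
MCID), EQUIVOCAL (contains 0 and the MCID). Boundary ties go to the
stronger category ("at or above the MCID" counts as meeting it).

Design-stage **power** uses the normal approximation
Φ(δ/(σ√(2/n)) − z₁₋α), one-sided α = 0.05 by default — this is the
convention under which a 40-patient pilot with δ = 5, σ = 20 has 20%
power; a two-sided 5% test would show ≈12%. Post-hoc power from observed
effects is deliberately not offered.

### Bayesian Go/No-Go

The mean difference θ gets a Normal prior; the observed d is a Normal
likelihood with *known* variance se² (Φ throughout, not t — the pilot SE
is treated as fixed). The posterior follows by precision additivity:

    1/s_post² = 1/σ_prior² + 1/se²,
    d_post    = s_post² (μ_prior/σ_prior² + d/se²).

The non-informative prior is an explicit zero-precision sentinel
(σ_prior = ∞), so posterior = observed holds exactly rather than
approximately. Priors are elicited from a mean and a symmetric central
interval: sd = (upper − lower)/(2 z₍(1+c)/2₎) with exact normal quantiles.
An interval not centred on the stated mean (beyond 1e−6) is rejected
rather than silently recentred, since it cannot be a Normal central
interval.

The decision quantity is P(θ > d_i | data) = Φ((d_post − d_i)/s_post) for
a threshold d_i, normally the MCID. Go requires this probability to
*strictly* exceed the pre-set hurdle (e.g. 0.75). Note the exceedance is
oriented so that a posterior mean far above the threshold gives a
probability near 1; sources sometimes typeset the argument with the
opposite sign, which would contradict their own numerical examples.

### Operating characteristics

`simulate_trial` draws control outcomes from N(0, σ²) and intervention
from N(δ, σ²) — fixing the control mean at zero loses nothing because
every downstream quantity depends only on the difference — and deletes
each observation independently with probability `missing_rate` (MCAR).
`go_rate` evaluates criteria over many replicates: a one-sided
frequentist criterion fires when p/2 < α with the difference in the
favourable direction, a two-sided one on p < α alone, and a Bayesian one
when the posterior exceedance clears its hurdle.

Randomness comes from a single Philox counter-based generator seeded once
per run; all replicates are drawn as one batch, so tables are
bit-reproducible. Truth scenarios share the replicate-level noise (the
intervention arm is a shared zero-mean draw shifted by δ), which makes
go-rates monotone in δ replicate by replicate. Replicates whose arms
collapse below n = 2 complete observations after dropout are redrawn from
a spawned child stream — keeping the replicate count exact — and counted
on the output table.

## Defaults and parameters

| parameter | default | rationale |
|---|---|---|
| MCID (SF-36 GH example) | 5 points | pre-specified clinically meaningful difference for the worked example |
| ladder levels | 0.50–0.95 step 0.05 | spans "suggestive" to conventional evidence |
| variance rule | pooled | reproduces standard two-sample t tables |
| go hurdle | 0.75 | "at least 75% sure of exceeding the MCID" |
| prior coverage | 0.90 | the usual elicitation phrasing ("90% certain within …") |
| power sidedness | one-sided α = 0.05 | screening-stage convention; see above |
| density grid | means ± 4·max SD, 512 points | covers >99.99% of each curve |

## What the synthetic generator does and does not emulate

It emulates the pilot's structure: two Normal arms of fixed size, a pure
location shift, and MCAR dropout at a constant rate (22.5% in the worked
example's spirit). It does **not** emulate skewed or bounded scores (real
SF-36 dimensions are bounded at 0/100 and often skewed), informative
missingness, clustering, or baseline covariates. A green simulation test
therefore establishes correctness of the decision machinery under the
Normal/MCAR ideal, not robustness to real-data violations of it.

## Numerical choices

- Exact normal quantiles everywhere (z₀.₉₅ = 1.6449…, never rounded
  1.645); t quantiles from scipy.
- sd of a single observation is defined as 0 so one-participant arms are
  representable; inference refuses arms with n < 2 or two zero-SD arms.
- Display rounding mirrors clinical reporting (effects/bounds 1 dp,
  p-values 3 dp, probabilities 2 dp); full precision is carried alongside
  in every report.
- Exceedance probabilities underflow to exactly 0/1 beyond ≈ ±8.3
  posterior SDs (double precision); strict-inequality go verdicts at such
  extremes behave accordingly.
- Reports serialize with sorted keys; identical config ⇒ byte-identical
  JSON.

## Known limitations

- The known-variance Normal Bayesian model ignores uncertainty in the
  pilot SD; with 31 observations a t-likelihood would give slightly wider
  posteriors.
- The t-test's simulated power differs from the normal-approximation
  design formula by ≈0.004 at 20/arm (exact noncentral-t power 0.1926 vs
  0.1965) — visible at Monte-Carlo precisions finer than ~0.004.
- Complete-case analysis is unbiased only under MCAR; the package
  deliberately offers no imputation.
- Two arms, continuous outcomes only; no sequential or adaptive designs.
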