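# Methods

## Valuation model

Single rewards follow the hyperbolic discount function V = A/(1 + kD)
with D in days and k in 1/day; bundles are valued additively,
V_bundle = Σ A_i/(1 + k D_i).  The model assumes a single k for all
rewards in both options — bundling is predicted to change cumulative
option value, not the discount rate itself — and no magnitude effect
(total amounts are held constant across bundle sizes by design, $1000
larger-later vs $500 smaller-sooner).

Money is integer cents at rest.  Rounding is round-half-up at cent
boundaries; `bundle_value` offers a full-precision mode (used for all
model work) and a cent-rounded-terms mode that reproduces
presentation-style arithmetic ($477.33 + $313.48 + $233.37 = $1024.18).
Time units: 1 h = 1/24 d, 1 wk = 7 d, 1 mo = 365/12 d, 1 y = 365 d; the
365-day year keeps the task's schedule arithmetic exact (715.30 d =
1.96 y; 715.30 × 9 / 365 = 17.64 y).

Totals are split into n installments as round-half-up(total/n) each,
with leftover cents applied one per installment starting at the middle
installment (1-based index ⌈n/2⌉) and alternating outward, later
neighbor first.  Both canonical 3-installment splits
($166.67/$166.66/$166.67 and $333.33/$333.34/$333.33) involve a single
correction cent and pin only the "middle first" part of the rule; the
outward order beyond that is this package's generalization and is
configurable (`residual_order`).

## Task engine

The five-trial adjusting-delay staircase is a binary search over a
closed index interval [0, 31] on a 32-value delay grid, presenting
delays[(low+high+1)//2] each trial; a larger-later choice raises `low`
to the presented index, a smaller-sooner choice lowers `high` below it.
Five halvings collapse 32 candidates to one, so the 2^5 choice
sequences biject onto the 32 grid indices.  For a deterministic
threshold chooser the procedure terminates at the largest grid delay
below the true crossing — a one-step downward discretization bias that
is inherent to the task and matters below.

The exact 32 delays are not a published list; the package's default
grid is anchored at the task's published constraints — 1 h minimum,
25 y maximum, 12 y second-largest, and 3 weeks as the first presented
delay (index 16, the first bisection midpoint) — with log-spaced
interior values (17 points from 1 h to 3 wk, 14 more to 12 y, then
25 y).  Any strictly increasing 32-vector can be substituted via
`DelayGrid` without code changes.  Whether 3 weeks is the 16th or 17th
ordered value is not pinned by the constraints; the bisection rule used
here places it at 0-based index 16.

Ties at exact value equality go to the larger-later option (arbitrary
but fixed, part of the chooser contract).  Left/right screen placement
is presentation-only and not modeled; recorded choices are semantic.

The appended quality-control trial offers both totals with all delays
removed (framed as installments at bundle sizes above 1); choosing the
smaller total flags inattention.

## Prediction

k is the reciprocal of the control-condition indifference delay (exact
for the 2:1 amount ratio).  The predicted first-installment delay D1*
solves Σ_{i=1..n−1} 1/(1+k·i·D1) + 2/(1+k·n·D1) = 1, obtained by
bracketed Brent root-finding on the reduced equation in x = k·D1
(relative tolerance 1e−12); D1* = x*(n)/k exactly, so predictions are
scale-invariant in k.  The reduced equation uses the exact 2:1 ratio of
equal splits; the ±$0.01 installment adjustments shift the root by
under 1e−4 relative and are deliberately ignored.  x*(3) ≈ 1.52860 and
x*(9) ≈ 2.45369, so at k = 0.01/d the predicted delays are ≈ 152.9 d
and 245.4 d.

The continuous root is snapped to the nearest grid delay.  "Nearest"
is measured in linear days by default (the plain reading); because the
grid is log-spaced and the analysis scale is log10 days, log-distance
snapping is available (`log_space=True`) and is less biased on the log
scale (see below).  Exact midpoint ties break toward the shorter delay.

Difference scores are predicted − observed log10 indifference delay:
positive means the additive model overestimated the bundling effect.
(The opposite subtraction order appears in some verbal summaries of
such analyses; this package fixes the convention stated here.)

## Synthetic cohorts

The generator emulates the study design: N = 252 participants (1:1
seeded assignment to ascending/descending bundle-size order), within-
subject bundle sizes {1, 3, 9}, a color catch item plus one no-delay
QC choice trial per condition, and heterogeneous discount rates
log10 k ~ Normal(−2.2, 0.9) per day.  The k distribution is a
documented generator assumption, not an estimate from any dataset.

No response model is prescribed by the design, so the generator states
its own: softmax on the additive value difference with a lapse mixture,
P(LLR) = logistic(β · ΔV / scale) where scale expresses ΔV per $100 of
the smaller-sooner total; with probability `lapse_rate` the choice is
uniform.  β = ∞ is the deterministic value maximizer.  Defaults
β = 4.0, lapse 0.02 produce orderly but noisy staircases — standard
practice in discounting psychophysics.

Inattentive agents (Bernoulli fraction of the cohort) answer the three
choice-QC trials uniformly at random and hence fail at least one with
probability 7/8.  The default fraction 0.136 therefore plants an
expected ≈ 30 QC failures per 252 participants — the exclusion rate
typical deployments of this task observe.  Attentive agents answer the
QC dominance check by strict value maximization (lapses are not
applied to it), so planted failures are attributable to the
inattentive fraction alone.  The color item is carried in the schema
and checked by the filter but never failed by generated agents,
matching its observed-in-practice zero failure rate.

Per-participant RNG streams are spawned from (seed, participant id),
so enlarging a cohort never reshuffles earlier participants, and a
config (seed included) reproduces a dataset byte for byte.

What the generator does *not* emulate: demographic covariates,
response times, within-session learning or fatigue, order effects
arising from carryover (the `order_effect_multiplier` applies a static
k multiplier to the descending group instead), and real humans'
deviation from the additive hyperbolic model itself.  Passing tests on
synthetic cohorts show the pipeline recovers the model where the model
is true; they say nothing about model adequacy for real respondents.

## Statistics

Indifference delays are log10-transformed (the base is pinned by the
published 2.85 ↔ 715.30-day correspondence).  The mixed ANOVA (within:
bundle size; between: order; interaction) is computed by pingouin with
no sphericity correction by default — matching the uncorrected
df convention (with 222 analyzed participants, within df (2, 440),
between df (1, 220)) — with Greenhouse–Geisser behind a flag.  Partial
η² = SS_effect/(SS_effect + SS_error).  Participants missing a
condition are excluded listwise with a warning.

Planned comparisons: paired t between bundle-size conditions and
two-sample t between order groups per condition, each family of three
Bonferroni-corrected (multiply by 3, cap at 1).

The one-sample TOST equivalence test uses the interval 0 ± 0.1·SD of
the difference scores (a negligible-effect bound that scales with the
sample's own spread).  Both one-sided tests must reject at α = .05;
the result also reports whether the 95% CI of the mean lies entirely
inside the interval, the equivalent CI-inclusion criterion.

Power for the within-between interaction uses the noncentral F with
λ = f²·N·m·ε/(1−ρ), df = ((g−1)(m−1)ε, (N−g)(m−1)ε), ε = 1 by default;
f = 0.10, ρ = .50, g = 2, m = 3 gives power 0.951 at N = 260.

## Discretization and equivalence: a known, quantified limitation

The task measures on a 32-value grid (log10 steps ≈ 0.17, and 0.32 at
the top).  With noise-free value-maximizing agents, the staircase's
downward rounding in the control condition propagates into k and hence
into the prediction, while the bundled condition is rounded
independently — except that the two rounding offsets are *perfectly
correlated* for a deterministic agent (their difference is
log10 x*(n) modulo the local grid step).  The result is a small,
persistent negative mean difference score (≈ −0.02 log10 units at
bundle size 3, ≈ −0.05 at 9) whose magnitude stays below the local
grid half-step but does not shrink with cohort size.  Because the TOST
interval is ±0.1·SD and the SD of near-noiseless diff scores is itself
small, equivalence is structurally unattainable in the deterministic
limit.

Moderate choice noise decorrelates the two roundings.  With β ≈ 8,
1% lapses, log-distance snapping and n = 600, the bundle-size-3
difference scores center on zero (|mean|/SD < 0.02) and TOST concludes
equivalence; the bundle-size-9 condition retains a ≈ −0.04 offset at
every noise level examined and remains non-equivalent.  A small mean
difference that nonetheless fails an SD-scaled equivalence test is
exactly the outcome pattern this design produces at realistic
measurement resolution, and the acceptance tests assert it as such.

## Problem sizes

Simulated cohorts in the test suite use 40–600 participants; the null
calibration of the ANOVA uses 300 replications of 20-participant
tables and the Bonferroni family-wise check 2,000 replications of
16-participant tables, sizes at which the binomial Monte-Carlo bands
(3σ) are far narrower than the asserted tolerances.  All suites are
seeded and deterministic.
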