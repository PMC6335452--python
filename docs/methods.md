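# Methods

## The behavioral paradigm being modelled

The package analyses two-option choice tasks in which a free, immediately
available small reward (SR) competes with a large reward (LR) that carries a
cost: physical effort (2, 4 or 6 dynamometer squeezes) in the *effort task*,
or waiting time (4, 7 or 10 s) in the *delay task*. Sessions have 60 trials:
30 *standard* trials, where the SR remains available throughout and a chosen
LR can still be abandoned mid-execution (an *opt-out*), and 30
*precommitment* trials, where the subject may first remove the SR from the
choice set, making the LR the only option. Each (trial type, cost level)
cell appears exactly 10 times, in a seeded uniformly shuffled order. Reward
magnitudes are subject-specific: items rated 0–10 are median-split after
discarding ratings ≤ 1, and `M_LR` / `M_SR` are the mean ratings strictly
above / below the median (at-median items belong to neither set — the split
is defined by strict inequalities, and we keep that literal).

## Models

Both model families share a hyperbolic-discounting core,

    SV(M, c; k) = M / (1 + k·c),

with `c` the effort or delay requirement and `k ≥ 0` the subject's effort
(ε) or delay (κ) discounting rate. The SR is free/immediate, so
`SV_SR = M_SR`.

**Motivation-maximization (MM) choice model.** The net motivational value of
the LR is its subjective value minus the opportunity cost of forgoing the
SR: `ΔV = SV_LR − M_SR`. Choice follows a softmax,
`P(LR) = 1 / (1 + e^(−γΔV))` with inverse temperature `γ ≥ 0`.

**Willpower (WP) choice model.** During choice the decision-maker wilfully
suppresses the tempting SR by a factor `ι ∈ [0, 1]` (0 = complete
suppression, 1 = none): `ΔV = SV_LR − ι·M_SR`. With `ι = 1` the WP model
reproduces the MM model exactly (the families are nested).

**Precommitment models.** Given subjective values fixed from the prior
choice-stage fits, the value of precommitting is

    MM:  V = SV_LR − SV_SR          (remove the opportunity cost of the
                                     *preferred* LR)
    WP:  V = ι_reward·SV_SR − SV_LR (precommit when even suppressed, the SR
                                     is anticipated to win — willpower
                                     failure)

and acceptance follows `P(precommit) = 1 / (1 + e^(−(θV + b)))` with
sensitivity `θ ≥ 0` and bias `b ∈ [−5, 5]`. We implement this formula
literally, so `b > 0` raises the probability of precommitting at `V = 0`.
The two models predict opposite cost dependence: under MM, precommitment is
most attractive for cheap LRs (V falls with cost); under WP, for expensive
ones (V rises with cost). That sign difference, not the parameter count
(both have two), is what makes the pair empirically distinguishable.

`ι` is estimated twice from the same trial subset: from the choice outcome
(`ι_choice`) and from the achieved-reward outcome (`ι_reward`, using
`P(LR achieved) = 1/(1 + e^(−γΔV))`). Opt-outs depress achievement below
choice, which the achievement fit absorbs as a *larger* ι — apparent
failure of suppression during execution. The WP precommitment model uses
`ι_reward` and the achievement-fit subjective values, as its hypothesis
dictates; they are inputs, never re-estimated.

## Fitting

Per subject × task × model, by maximum likelihood:

* **Data subsets.** Choice models (and the achievement fit): standard trials
  plus precommitment trials with precommitment rejected — the trials where
  the LR-vs-SR choice was actually faced. Precommitment models: all 30
  precommitment trials, outcome = the accept/reject decision.
* **Objective.** The optimizer minimizes the exact Bernoulli
  negative log-likelihood on the logit scale (softplus form), which stays
  smooth deep into saturation; reported log-likelihoods use probabilities
  clamped to `[1e−12, 1 − 1e−12]` so they are finite for any bounded
  parameter vector. (Optimizing the clamped objective directly is a trap:
  it goes flat at the clamp while its gradient does not, and L-BFGS-B
  stalls at saturated starting points.)
* **Bounds.** ε, κ, ι ∈ [0, 1]; γ, θ ∈ [0, 100] (the upper bound leaves
  ample headroom above empirically observed temperatures while keeping the
  start box finite); b ∈ [−5, 5].
* **Multi-start.** L-BFGS-B with analytic gradients from `n_starts = 20`
  points (box midpoint + 19 seeded uniform draws), `ftol = 1e−8`. Exact
  likelihood ties are broken by the lexicographically smallest parameter
  vector, so fits are deterministic given the seed.
* **Reliability.** A fit is flagged unreliable when fewer than two starts
  agree with the best log-likelihood within `1e−3`, or when the outcome has
  no variance in the fitted subset (e.g. all-LR choosers, for whom ι is
  unidentifiable). This operationalizes a screen whose exact criterion is
  not published; it is deliberately conservative.
* **Summaries.** BIC = `k·ln(n) − 2·lnL`; McFadden pseudo R² against a
  fixed chance null `lnL₀ = n·ln(0.5)` (a coin-flip predictor, not an
  intercept-only fit — the natural null for binary forced choice); percent
  correct at the 0.5 threshold.

Model comparison is fixed-effects: group BIC is the sum of per-subject
BICs, lower wins, and an absolute group difference above 2 counts as
positive evidence. Parameter contrasts (pseudo R², ι_choice vs ι_reward,
θ_MM vs θ_WP) are two-tailed paired t-tests; the θ contrast can exclude
subjects who always or never accepted precommitment, for whom θ is pinned
by the likelihood plateau. Zero-variance contrasts return NaN p-values
with a warning rather than raising.

## Synthetic cohorts

Because no trial-level data ship with the package, every analysis is
exercised on simulated cohorts whose generative process composes exactly
the equations above. Per subject: a rating session (400 integer ratings,
discretized normal around mid-scale, giving `M_LR ≈ 7.5`, `M_SR ≈ 3.5`
after the median split), choice parameters, precommitment parameters, and
two lapse processes — an opt-out probability per LR choice (defaults 0.005
effort / 0.017 delay, the empirically observed standard-trial rates; the
lapse ignores cost because nothing finer is known) and an
achievement-failure probability (default 0, i.e. honest effort succeeds).
After accepted precommitment the SR is gone, so choice is forced to LR with
no second softmax draw and no opt-out.

Default parameter priors are truncated normals centred on the published
group estimates of the study population this generator emulates (ε ≈ 0.21,
κ ≈ 0.16, γ ≈ 6.6 effort / 20.7 delay, ι ≈ 0.49, θ ≈ 3.7 / 5.7,
b ≈ −1.5 / −1.1) with spreads set to the implied between-subject standard
deviations (s.e.m. × √58), truncated to the fitting bounds. The
precommitment bias is coupled across tasks within subject (a shared
deviation carrying 75 % of the prior s.d.), giving a cross-task rank
correlation of the *true* b around 0.55. The correlation of *fitted* b is
substantially attenuated — 30 precommitment trials identify b only
loosely, and θ–b trade-off plus boundary pinning for always/never
precommitters inject task-specific noise — so it fluctuates around the
mid-0.3s across seeds and can be much lower in single cohorts. Emergent
precommitment rates land near 40–50 %, opt-out rates at the configured
0.5 % / 1.7 %.

What the generator does *not* emulate: response times, fatigue or
time-on-task drift, cost-dependent opt-outs, rating drift, and any
within-session parameter non-stationarity. Passing tests therefore
validate the estimation machinery on data that satisfy the models'
assumptions; they cannot certify those assumptions for real behavior.

## Parameter and model recovery

`recovery_study` and `recovery_study_uniform` run simulate-then-refit loops
and summarize bias, RMSE, Spearman ρ(true, recovered) and the unreliable
fraction per regime. At 600 trials/subject with ε ∈ [0.1, 0.4] and
γ ∈ [3, 20], the discount rate recovers with |bias| < 0.03 and ρ > 0.9;
at the study's 60 trials it is noisier but rank-faithful. Temperature
recovers poorly whenever no cost level lands near indifference (perfect
separation pushes γ to its bound) — an identifiability ceiling of the
3-level design, not an optimizer failure.

The known ι pathology is reproduced deliberately: at ε ≈ 0 the LR's value
is barely discounted, the LR dominates every offer, choices lose variance,
and ι cannot be estimated; `flag_degenerate_subjects` recognizes such
subjects by all-LR (or all-SR) choice records in the choice-model subset.

**An asymmetry the user should know about.** Over only three cost levels
the two-parameter MM choice family reproduces essentially any WP
choice-probability profile (expected log-likelihood gap < 0.05 nats over a
44-trial subset, versus a BIC penalty of ln 44 ≈ 3.8 for WP's extra
parameter). From choice data alone, then, BIC prefers MM regardless of the
generative model — the honest consequence of near-unidentifiability plus
parsimony. A WP agent's generative signature lives in its *precommitment*
decisions, whose acceptance rises with cost where MM predicts the
opposite; there both models carry two parameters and BIC reduces to a pure
likelihood comparison. `model_recovery_study` therefore scores a cohort as
correctly recovered when the BIC comparisons identify its generative
hypothesis: for MM cohorts both the MM choice and MM precommitment models
must win; for WP cohorts the WP precommitment model must win.

## Model-free statistics

LR achievement is analysed with a GEE logistic regression (subject as
cluster) on trial type and cost level, both categorical. Candidate working
correlations are independence and exchangeable, scored by QIC with the
binomial scale fixed at 1; Wald χ² per term and per-cell predicted
probabilities with delta-method standard errors are reported. An optional
trial-type × cost interaction term exists mainly to show it worsens QIC.
Calibration of the Trial-Type Wald test is checked on null cohorts built
from never-precommitting agents — a rejected precommitment trial is, by
task design, identical to a standard trial, so with acceptance probability
forced to zero the trial-type labels are exchangeable and any rejection is
a false positive. Null cohorts use 40 subjects × 18 trials: large enough
in clusters that the sandwich-variance Wald test is near its nominal
level (robust GEE inference is known to be anticonservative with few
clusters), small enough per subject to keep 500 replicates cheap.

Behavioral rates use their natural denominators: precommitments over
precommitment trials, opt-outs over standard-trial LR choices; undefined
rates are NaN, never 0. The per-subject *precommitment benefit* is the
relative increase in achieved LRs on precommitment versus standard trials.
Cross-task association (of fitted b, of the benefit) is Spearman rank
correlation, two-tailed.

## Power utility

`required_sample_size` returns the smallest n for which a paired t-test
reaches the target power, computed exactly from the noncentral t
(df = n − 1, noncentrality d_z·√n) with geometric bracketing plus binary
search. For d_z = 0.5, α = 0.05 two-tailed, power 0.95 it returns 54.

## Determinism and numerical choices

Every stochastic stage derives its seed from a global seed via
`numpy.random.SeedSequence` (with crc32-hashed stage labels, stable across
processes); reruns of any stage with the same (config, seed) are
bit-identical. Logistic probabilities are evaluated with `scipy.special.expit`
(overflow-safe); likelihoods as described above; paired tests with zero
variance warn and return NaN rather than raising.

## Problem sizes used by the shipped analyses

The repository's own end-to-end runs use: 58-subject cohorts at 60
trials/task (the study scale) for fitting and comparison; 50 replicates at
600 trials for asymptotic parameter recovery; 20 cohorts for model
recovery; 500 null simulations at 40 × 18 trials for the calibration
check. These sizes give stable Monte-Carlo summaries on a single CPU and
are all configurable.

## Known limitations

* Only hyperbolic discounting is implemented; exponential or parabolic
  cost functions would need a new valuation kernel.
* Fitting is subject-wise maximum likelihood; no hierarchical shrinkage.
* The MM/WP choice pair is near-unidentifiable from 3-cost-level choice
  data (see above); conclusions about willpower at the choice stage rest
  on parsimony, in the synthetic setting as in the original design.
* The GEE cell predictions are population-averaged; no subject-level
  random effects are produced.
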