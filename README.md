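# precom

Computational modelling of **precommitment** in effort-based and delay-based
choice: why do people voluntarily remove a tempting easy option from their
own future choice set?

The package implements, fits and compares two generative accounts of
behavior in a two-option paradigm where a free/immediate small reward (SR)
competes with a large reward (LR) that costs physical effort (dynamometer
squeezes) or waiting time, and where half of the trials offer the option to
*precommit* — to eliminate the SR before choosing:

* **Motivation maximization (MM)** — choices follow the net motivational
  value `ΔV = SV_LR − M_SR` with hyperbolic discounting
  `SV_LR = M_LR / (1 + k·cost)`; precommitment is worth
  `V = SV_LR − SV_SR`, i.e. it removes the opportunity cost of a
  *preferred* LR.
* **Willpower (WP)** — the SR is wilfully suppressed during choice,
  `ΔV = SV_LR − ι·M_SR` with `ι ∈ [0, 1]`; precommitment is worth
  `V = ι_reward·SV_SR − SV_LR`, i.e. it pre-empts an anticipated failure
  of suppression.

Choice and precommitment probabilities are softmax:
`P(LR) = 1/(1+e^(−γΔV))`, `P(precommit) = 1/(1+e^(−(θV+b)))`.

Since no trial-level human data are distributed, the package ships a
first-class **synthetic cohort generator** that emulates the study design
(60 trials/task: 30 standard + 30 precommitment, 3 cost levels × 10
repetitions, subject-specific reward magnitudes from a rating median
split, rare opt-outs), so the entire estimation and comparison machinery
is testable end-to-end and validated by parameter recovery.

What's inside (`src/precom/`):

| module | role |
| --- | --- |
| `valuation` | the value and probability equations (pure functions) |
| `design` | task designs and rating-based reward sets |
| `cohort` | synthetic agents and trial simulation |
| `models` | scikit-learn-style estimators `ChoiceModel` / `PrecommitModel` (bounded multi-start MLE) |
| `fitting` | per-subject fitting cascade on the correct trial subsets |
| `comparison` | group BIC, McFadden pseudo R², paired contrasts |
| `model_free` | GEE repeated-measures logistic regression (QIC-selected working correlation), behavioral rates, Spearman cross-task correlations |
| `recovery` | parameter/model recovery and the degenerate-subject screen |
| `power` | exact noncentral-t sample-size calculation |
| `pipeline`, `cli` | end-to-end orchestration and the `precom` command |

## Worked example

```python
from precom.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=3, n_subjects=58, n_starts=8))
print(report.summary())
```

```
== pipeline run ==
[effort] precommit rate 0.431, opt-out rate 0.005
[effort] choice models:
  model comparison: mm_choice vs wp_choice
    group BIC   mm_choice: 1085.4   wp_choice: 1306.8   delta: -221.4
    mean pseudoR2   mm_choice: 0.836   wp_choice: 0.836
    winner: mm_choice (positive evidence)
    paired t (iota_choice_vs_iota_reward): t(57) = -0.524, p = 0.6024
[effort] precom models:
  model comparison: mm_precom vs wp_precom
    group BIC   mm_precom: 959.8   wp_precom: 1764.9   delta: -805.1
    mean pseudoR2   mm_precom: 0.736   wp_precom: 0.378
    winner: mm_precom (positive evidence)
    paired t (theta_mm_vs_wp): t(53) = 8.348, p = 0.0000
...
cross-task Spearman bias_b: rho = 0.344, p = 0.0082
cross-task Spearman precommitment_benefit: rho = 0.460, p = 0.0106
```

Reading this: the cohort was simulated from MM agents, and the analysis
correctly recovers that — the MM choice model wins the group BIC purely on
parsimony (identical pseudo R², one fewer parameter), the MM precommitment
model wins decisively on likelihood, the ι contrast is null as it should
be when opt-outs are rare, and the subject-level precommitment bias `b`
rank-correlates across the effort and delay tasks because the generator
couples it within subject.

The same analyses run from the shell:

```bash
precom power -d 0.5                 # -> required n = 54
precom simulate --n-subjects 58 --seed 3 --out trials.csv --params-out truth.json
precom modelfree trials.csv
precom recover --model mm_choice --trials 600 --n-reps 20 --seed 1
precom run --seed 3 --output-dir out/
```

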