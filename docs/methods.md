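# Methods

## The behavioural model

`ewalearn` models choice behaviour on a two-armed probabilistic
reversal-learning task with the experience-weighted attraction (EWA)
learning rule. The task runs 80 trials; one stimulus carries an 80%
chance of positive feedback and the other 20%, and the contingency flips
once at the 40th trial (40 discrimination + 40 reversal trials).

Two quantities evolve per participant:

* experience weight `N(t) = ρ·N(t−1) + 1`, `N(0) = 1`. The memory rate
  ρ ∈ [0, 1] sets how much accumulated experience counts: ρ = 0 reduces
  the model exactly to Rescorla–Wagner (N ≡ 1), ρ = 1 weighs all past
  trials (N(t) = t + 1).
* attractions `A_j(t) = [(1−α)·N(t−1)·A_j(t−1) + I_j] / N(t)`,
  `A(0) = 0`, where the learning rate α ∈ [0, 1] sets how fast the last
  outcome displaces history, and the reinforcement indicator `I_j` is +1
  only for the chosen stimulus when positive feedback arrives. Both
  stimuli are updated every trial (the unchosen one simply decays).

Choices follow the power-form rule `P_j ∝ A_j^β`, with the exploration
rate β ≥ 0 acting as an inverse temperature: β = 0 is uniform random
choice, large β is near-deterministic exploitation.

### The attraction floor

The all-zero initial state makes the power rule 0/0, and a literal zero
attraction gives a never-rewarded option exactly zero choice
probability. Attractions are therefore floored (choice rule only, never
in the update) at `ATTRACTION_FLOOR = 0.1`. The floor is not a numerical
afterthought: it is the effective attractiveness of an untried option,
and it controls how often a simulated agent explores. We calibrated it
against the behavioural summary statistics of human cohorts on this
task: at population-typical parameters (α ≈ 0.63, ρ ≈ 0.33, β ≈ 1.5) the
0.1 floor yields discrimination-phase error rates ≈ 0.20 and
reversal-phase error rates ≈ 0.23, in the range reported for real
participants, with realistic post-reversal switching. A much smaller
floor (say 1e−6) makes the untried arm's probability ≈ (1e−6/A)^β ≈
1e−9, so agents lock onto the first rewarded arm, never adapt after the
reversal (error rate ≈ 0.73), and leave β unidentifiable — we consider
that regime a mis-specification of the generative model rather than a
defensible reading of the choice rule. The constant is module-level and
can be changed by users studying floor sensitivity.

### Fitting windows

The default likelihood window is the reversal phase (trials 41–80), with
the learning state re-initialised to A = 0, N = 1 at the window start —
the reproducible reading of "fitting the reversal phase" when carry-over
is unstated. Two alternatives are provided: `all` (full session) and
`reversal_carryover` (state carried from trial 1, likelihood summed over
reversal trials only). In recovery pilots carry-over changed estimates
only marginally, so the simpler re-initialised window remains the
default.

## Hierarchical Bayesian estimation

Each participant's parameters live on an unconstrained scale θ = (θ_α,
θ_ρ, θ_β) with probit transforms α = Φ(θ_α), ρ = Φ(θ_ρ) and a scaled
probit β = 10·Φ(θ_β). The 10 upper bound comfortably covers empirically
observed exploration rates (≈ 1.5 ± 0.5) while keeping the person-level
Normal prior as written. The hierarchy is

* θ_ip ~ Normal(µ_p, σ_p) per parameter p,
* µ_p ~ Normal(0, 10), σ_p ~ half-Cauchy(0, 5).

### Sampler

Sampling uses a blocked adaptive Metropolis-within-Gibbs scheme built
around the model's conditional-independence structure, with four
independent chains (default 4 × 1000 kept iterations after 1000 warm-up
iterations, all configurable including thinning):

1. per-participant random-walk Metropolis on θ, one parameter at a time,
   vectorised across participants and chains; proposal scales adapt
   during warm-up toward 0.35 acceptance (Robbins–Monro, decaying
   learning rate);
2. exact conjugate Gibbs draws for each µ_p;
3. stepping-out slice sampling for each σ_p on the log scale;
4. per-parameter *translation* moves (µ_p and all θ_ip shifted together;
   person-level prior terms cancel) and *rescale* moves (σ_p and all
   deviations scaled together, with the c^n Jacobian), each proposed
   with a mixture of short and long jump scales. These keep the
   population location and scale mobile where the likelihood is nearly
   flat in a parameter — without them the population blocks mix an order
   of magnitude slower.

Chains are initialised at jittered coarse-grid per-participant maximum
likelihood estimates, clipped to |θ| ≤ 2.5. Beyond |θ| ≈ 3 the probit
transforms saturate and the likelihood becomes flat, forming a plateau a
randomly initialised chain can wander onto and take very long to leave;
anchored initialisation avoids that while the jitter keeps chains
overdispersed.

Correctness of the sampler was verified by a prior-recovery experiment:
with the likelihood forced flat, the sampled µ match Normal(0, 10) and
the sampled σ match half-Cauchy(0, 5) (quartiles and a KS test on the
probability transform).

### Diagnostics, MAP estimates, WAIC

Convergence is summarised by the split-chain potential-scale-reduction
statistic (R-hat), computed for every hyperparameter and as a maximum
over person-level quantities; zero-variance draws return 1 by
convention. A run with any monitored R-hat ≥ 1.1 is flagged
(`converged = False`, a warning, and a non-zero exit from the CLI), not
silently returned.

Per-participant point estimates are posterior *modes* on the constrained
scale, located by a Gaussian KDE over pooled draws (256-point grid over
the draw range; subsampled to ≤ 1000 draws for cost). The alternative
`method="joint_draw"` — the single kept draw with the highest joint
model log-density — is retained but not the default: in a posterior with
~150 dimensions the best kept draw is still a typical draw in every
single coordinate, so it carries each participant's full posterior
spread as noise and measurably attenuates downstream correlations
(pilot: corr(true β, estimate) ≈ 0.2 vs ≈ 0.5 for mode/mean on identical
draws).

WAIC is computed on the deviance scale, `−2·(lppd − p_waic)`, with the
variance-form penalty (population variance over draws, matching the
reference implementation it is tested against) on per-trial pointwise
log-likelihoods from an evenly thinned subset of at most 1000 draws.

### What the posterior geometry looks like

Two honest features of this model at task scale are worth knowing:

* ρ is weakly identified. The reversal-window likelihood penalises high
  ρ but is nearly flat toward ρ → 0 once α co-adapts, so the population
  posterior for (µ_ρ, σ_ρ) includes a large plateau; its R-hat converges
  slowest and per-participant ρ estimates carry little signal at 40
  trials (grid-MLE recovery corr ≈ 0.1).
* per-participant β reliability is capped by the data. With 40 binary
  choices, both an unregularised grid MLE and the hierarchical posterior
  mean recover corr(true β, estimate) ≈ 0.5–0.65. Any analysis
  correlating estimated β with an external measure is attenuated by that
  factor; at study scale an induced latent correlation of −0.42
  reproduces as roughly −0.25 to −0.30. This is an information limit of
  the design, not of the estimator.

## Synthetic cohort generator

The generator emulates every measurement channel the analysis consumes.

* **Parameters.** θ_i ~ Normal(µ_pop, σ_pop) on the unconstrained scale
  shared with the fitter. Defaults place the constrained population at
  α ≈ 0.63, ρ ≈ 0.33, β ≈ 1.5 with spreads (latent 0.50/0.55/0.20)
  matched via the delta method to between-participant SDs of roughly
  0.19 (α), 0.21 (ρ) and 0.45 (β) — the scale reported for student
  cohorts on this task.
* **Behaviour.** One EWA agent session per participant on the 80-trial
  task (choices by inverse-CDF over the choice probabilities, feedback
  from the 80:20 rule).
* **Questionnaires and interoception.** A Gaussian copula ties measures
  to parameters: each measure's standard-normal latent is a linear
  combination of the standardised parameter latents with coefficients
  equal to the requested Pearson correlations plus independent residual
  noise, so latent-scale targets are hit exactly in expectation; a
  measure whose squared loadings exceed 1 is rejected as infeasible.
  Observed scores are produced last — location/scale mapping, clipping
  to the instrument range (CES-D 0–60, DAMS-D 3–21, PANAS subscales
  8–48) and integer rounding — so targets always refer to the latent
  scale. Default targets reproduce the salient baseline associations
  (DAMS-D×β −0.419, PANAS-PA×α 0.368, attention×β 0.361, CES-D×β −0.240,
  awareness×β 0.233).
* **Heartbeat counting.** Three trials (25/35/45 s at 70 bpm). The
  relative miscount is (1 − a) times a mean-one gamma multiplier
  (shape 25) with random sign, so the expected Schandry accuracy score
  equals the true awareness a; a = 1 reproduces the count exactly.
* **Probe detection.** 4 emotion blocks × 36 trials, half internal /
  half external probes, SOAs balanced over 2.25/3.0/3.75 s. External RTs
  are Normal(0.43 s, 0.05 s); internal RTs sit `true_attention` seconds
  lower. Gross lapse outliers (+1–3 s) are injected at rate 0.02 to
  exercise the Grubbs filter. Emotion-block effects on RT are zero by
  default (the analysis does not use them).

What the generator does **not** emulate: sequential dependencies in RTs,
heart-rate variability and trial-duration effects on counting accuracy,
questionnaire item-level structure (totals are generated directly), any
effect of the (unsuccessful) interoception manipulation, and any true
group difference — groups are labels over one population. Passing tests
therefore demonstrate internal consistency of the pipeline under the
stated generative assumptions, not validity on real human data.

## Psychometric scoring

* **Heartbeat score**: mean over trials of 1 − |actual − reported| /
  actual. The raw signed-sum variant (no absolute value, no 1−·) is
  available behind `raw=True`; it is not the default because it can
  reward systematic overcounting and does not live on the 0–1 accuracy
  scale that observed group means (≈ 0.56–0.67) occupy. Scores below 0
  (reported > 2× actual) are not clipped; they propagate to the arcsine
  step, which clips with a warning.
* **Grubbs filter**: iterative two-sided Smirnov–Grubbs at α = 0.05 by
  default, applied within each probe type; the critical value uses the
  exact t-quantile form and is tested against published tables.
  Zero-variance and n < 3 samples pass through unchanged.
* **Attention score**: mean(external RT) − mean(internal RT) after
  filtering, in seconds (observed magnitudes ≈ 0.02–0.03 are only
  consistent with seconds).
* **Questionnaires**: reverse-keyed items map x → min + max − x before
  summation. DAMS-D uses range 3–21 (3 items × 7-point scale; a printed
  range of 3–27 is inconsistent with the item count and is taken as a
  typo). Cronbach's alpha uses the standard k/(k−1) variance form.

## Statistics

Student's pooled-variance t (two groups of 27 and 25 give the df = 50
seen in published tables — Welch would not), Pearson chi-square without
continuity correction (reproduces the printed χ² = 0.02 for the gender
table; Yates does not), Pearson correlations with t-based two-sided
p-values and the flag legend *** p<0.001 / ** p<0.01 / * p<0.05 /
† p<0.10, a 2×2 mixed-design ANOVA interaction (pingouin; equal to the
squared difference-score t in this design, which the tests exploit as an
oracle), and pairwise deletion for missing values. No multiple-testing
correction is applied by default, matching the original single-test
convention; a Holm option exists.

Interoceptive awareness is arcsine-square-root transformed before
entering correlations.

## Problem sizes used in the test suite

The acceptance suite fits (i) 40 agents × 200 trials (4 chains, 1500
warm-up, 500 kept × thin 3) for population-mean coverage, (ii) 50 agents
on the 40-trial reversal window for β recovery, and (iii) a 500-agent
cohort at reduced iterations (800 warm-up, 300 kept × thin 2) for the
pipeline correlation recovery; Monte-Carlo calibrations use 10,000
feedback draws and 1000 null ANOVA replicates. These sizes keep the full
suite around ten minutes on one CPU while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* ρ's weak identifiability (above) makes its population scale drift to
  large values on the flat side; runs flag µ_ρ/σ_ρ R-hat first.
* The sampler is gradient-free; for much larger cohorts or longer
  sessions an HMC implementation would scale better per effective
  sample.
* The generator draws actual heartbeats at a fixed 70 bpm and does not
  model individual heart-rate differences.
* Single reward channel: no separate punishment learning rate; reward
  and punishment sensitivity are not separable in this parameterisation.
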