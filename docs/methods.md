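# Methods

This note documents the models, numerical choices and limitations behind
`biasdissect`. It is the package's own account of its science; every
empirical number quoted here is one the test suite or
`scripts/acceptance.py` computes at run time.

## The paradigm being emulated

Observers view a 350 px reference line and then target lines drawn from
two five-value distributions centred at the reference length ± a
per-subject threshold. On each trial they either categorize the target as
*shorter* or *longer* than the reference (decision task) or reproduce its
length (reproduction task); in the decision-only variants every trial is a
categorization with a recorded reaction time. Three manipulations bias the
choice toward one category:

* **Müller-Lyer** — arrowhead flankers that change the *apparent* length
  of the target;
* **base rate** — a 3:1 prevalence of one category;
* **payoff** — losing 5 points for one error type and 1 point for the
  other (2/4 in the first decision-only experiment).

The scientific question the tooling serves is whether a given criterion
shift is perceptual (it should move reproductions as well as choices, and
load on the diffusion model's drift criterion at all response speeds) or
decisional (choices only, loaded on the starting point and concentrated in
fast responses).

## Staircase and stimulus distributions

Difficulty is titrated with a weighted up-down staircase targeting 75%
accuracy. The offset starts at 20 px; after a correct response it shrinks
by the down step, after an error it grows by the up step, with up:down =
0.75 : 0.25 = 3 : 1, the equilibrium condition for a 75% convergence
point. The published description of the procedure does not state the step
schedule, so the package uses a 4 px initial base step shrinking
geometrically (×0.85 per reversal) to a 1 px floor; the threshold is the
mean offset at the last 20 of 25 reversals. Reversal averaging with
asymmetric steps carries a small negative bias: across 200 seeded runs the
accuracy implied by the returned threshold averages ≈74%, within the
±3-percentage-point calibration band the pipeline checks.

The five-value target distributions are likewise under-specified in prose
("normal five-value distributions"); the package uses values
`centre + {−2,−1,0,1,2}·(threshold/4)` with binomial(4, ½) weights
(1 4 6 4 1)/16 — a discrete normal-shaped distribution whose mean equals
the centre exactly. Both choices are configurable.

## The SDT-style observer

`ObserverSDT` draws a percept `target + perceptual_shift + N(0, σ_enc)`,
answers *long* when the percept exceeds
`reference + criterion_shift + N(0, σ_crit)`, and reproduces
`percept + N(0, σ_repro)`. Perceptual shifts exist only in the
Müller-Lyer condition and criterion shifts only in payoff/base-rate — the
generator's ground truth *is* the dissociation the analysis stack must
recover, which is what makes end-to-end recovery tests meaningful.

The split of discrimination noise into an encoding part σ_enc (shared
with reproduction) and a criterion-jitter part σ_crit (choice only) is
deliberate. A single shared noise source calibrated to 75% accuracy caps
the target–reproduction correlation near 0.56, visibly below the ≈0.71
rank correlation characteristic of this paradigm; attributing part of the
2AFC noise to the comparison/memory stage rather than to encoding is both
psychophysically standard and necessary to reproduce that correlation.
Defaults (σ_enc = 24 px, σ_crit = 37.4 px, σ_repro = 14 px) give a total
discrimination SD of 44.4 px — a 75% point near 30 px, comfortably inside
the staircase's range — and a mean per-subject Spearman ρ ≈ 0.71 at the
calibrated difficulty. The default ±8 px perceptual shift (Müller-Lyer)
and ±10 px criterion shift (payoff/base-rate), with 8 px between-subject
SDs, produce long-minus-short effect sizes of the order the paradigm
reports (Cohen's d roughly 0.6–1.1 for criterion; ≈1 for Müller-Lyer
reproduction; ≈0 for payoff/base-rate reproduction).

What the generator does **not** emulate: sequential effects and learning
across blocks, lapses correlated with RT, motor noise that scales with
length, and screen-resolution heterogeneity. Passing recovery tests
therefore shows the analysis stack is correct under the stated observer
models, not that real observers satisfy those models.

## Signal detection analysis

d′ = Z(HR) − Z(FAR) and c = ½(Z(HR) + Z(FAR)) with hits = correct *long*
responses. Note the criterion is implemented exactly as the paradigm
defines it, **without** the conventional minus sign: higher c means more
*long* responses, the negative of the textbook convention. Degenerate
rates (0 or 1) are corrected by adding 0.5 to every count in the affected
cell (log-linear rule), applied only when needed. The long-minus-short
effect uses the paired Cohen's d (mean/SD of differences); a zero SD
yields an explicit undefined flag rather than ±∞. Exclusions follow the
two-stage rule: d′ ≤ 0 first, then any tracked quantity beyond 4 SD of
the sample mean.

Conditional bias functions bin each subject × condition cell's RTs into
quintiles (type-7 quantiles, boundary ties to the lower bin), compute c
within each bin from that bin's own rates, and only then average over
subjects — pooling before binning is a documented error mode covered by a
regression test. ρ is Spearman's rank correlation (Pearson available),
since "rho" conventionally denotes Spearman.

## Ordinal Bayes factors

Each between-subjects condition contributes per-subject long-minus-short
differences x ~ N(μ_c, σ_c²). With Jeffreys' prior on σ_c² and a Cauchy
(JZS) prior of scale r = √2/2 on δ_c = μ_c/σ_c, the likelihood of δ
depends on the data only through the t statistic (a noncentral-t
density). The t-test Bayes factor is the 1-D integral of that likelihood
ratio over the prior, evaluated by adaptive quadrature; the posterior of
δ is sampled i.i.d. by dense-grid inverse-CDF inversion of the same 1-D
density (no MCMC error outside the constraint-counting step; effective
sample size equals the draw count by construction).

Ordinal models are scored with the encompassing-prior identity
BF(constrained vs unconstrained) = P(constraint | posterior) /
P(constraint | prior), counted on unconstrained draws. Equality-to-zero
constraints remove the effect (nested-model BF via the same quadrature);
equality between conditions shares a single δ across their noncentral-t
likelihoods. The named models are: **null** (all effects 0), **A** (all
three effects positive), **C** (Müller-Lyer positive, others 0), **GG**
(payoff = base-rate, both larger than the Müller-Lyer effect, all
positive; prior constraint probability 1/8). Every counted BF carries a
Monte-Carlo standard error on the log scale; quadrature components are
treated as exact at their 1e-8 tolerance.

## Drift-diffusion machinery

Within-trial diffusion SD is fixed at 1 (the modern convention — all
parameter magnitudes are on that scale). The upper boundary is the *long*
response (stimulus coding): the per-trial mean drift is
`sign(category)·v + dc`. First-passage densities use the classic dual
series expansion with automatic small-time/large-time switching at a
1e-12 truncation error for density evaluation and 1e-9 inside the
sampler. Across-trial drift variability `sv` enters analytically through
the Gaussian-mixture factor, so the likelihood never needs per-trial
augmentation. The simulator uses Euler steps (default dt = 1e-4 s) with
exact Brownian-bridge crossing probabilities between grid points, removing
the leading-order discretization bias; runaway trials are truncated at 20 s
and counted. RTs are in seconds; the contaminant filter removes RTs below
0.2 s and then above mean + 4 SD of the experiment sample.

### Hierarchical model

Default sharing map: z and dc vary over bias source × direction; a, v, t0
over bias source only; one group-level sv. Subject parameters are normal
around condition-cell means on transformed scales (log a, logit z,
identity v/dc/t0, t0 truncated below each subject's minimum RT through the
likelihood). Hyperpriors are weakly informative: normal mean priors
(log 1.5 ± 1 for log a, 0 ± 3 for v, 0.3 ± 0.5 s for t0, 0 ± 1 for
logit z, 0 ± 2 for dc) and half-normal(0.5) group SDs and sv; all are
recorded in the fit object.

Sampling is Metropolis-within-Gibbs: adaptive random-walk updates for
subject parameters (adaptation during burn-in only), conjugate draws for
group means, log-scale random-walk for group SDs and sv, plus two
auxiliary moves that are essential at desk scale: a joint translation of
a group mean with its subjects' values, and an interweaved non-centred
rescaling of subject deviations together with the group SD. The
rescaling move is run twice per sweep; without it the group SDs (whose
posteriors concentrate near zero when pooling is strong) mix far too
slowly for the short schedule.

The fidelity schedule is 3 chains × 30,000 samples, 9,000 burn-in,
thinning 2 (10,500 retained per chain). The package default is the same
arithmetic at desk scale: 3 × 4,000 with 1,000 burn-in and thinning 2
(1,500 retained per chain), which the test suite uses together with
10-subject × 400-trial synthetic cohorts; on those problems all
group-level Gelman-Rubin statistics (classic between/within ratio) fall
within the 0.99–1.01 band and the key contrasts are recovered with the
complementary parameter's interval covering zero. Posterior predictive
checks re-simulate each subject's trial set under posterior parameter
draws (default 500) and compare choice proportions and RT quantiles
(.1/.3/.5/.7/.9) per design cell.

The conditional-bias-function dissociation checks run on larger
simulator-direct datasets (20 subjects × 2,000 trials) than the MCMC
recovery checks, because the quintile-binned criterion is far noisier than
the fitted contrasts; the flat-vs-declining thresholds (|Q1−Q5| < 0.15
vs > 0.3 on the long-minus-short criterion) were frozen from large-n
simulation before being asserted.

### Known limitations

* The sampler is a random-walk scheme: adequate and verified at the sizes
  above, but slower-mixing than gradient-based samplers on much larger
  cohorts; the Ȓ contract should be re-checked when scaling up.
* sv is shared across an experiment's subjects and sources ("group
  level"); per-source sv is not implemented.
* Inter-trial variability of z and t0 is not modelled, and the
  reproduction task is outside the diffusion model (in the two-task
  paradigm the post-stimulus task prompt erases the RT signature anyway).
* The starting-point sign in Müller-Lyer-like conditions is treated as
  unconstrained in recovery tests: fast error dynamics opposite to the
  bias direction are known to be imperfectly recovered by this model
  class.

## Pipeline and reproducibility

Experiment presets (YAML, shipped with the package) hold every study
constant: 350 px reference, 5–9 px jitter (absent in decision-only
experiment 1), 3:1 base rate, 5/1 penalties (2/4 in experiment 1),
arrowhead lengths 30/40/50/60 px, fixation timings, the 40 px
reproduction-feedback threshold, trial counts and staircase schedules.
Preset subject counts mirror a plausible post-exclusion cohort
(46/44/48 for the reproduction experiment); analyses in the test suite
run on smaller cohorts, with sizes stated where they are used. Config
validation is by explicit key/type checks in `pipeline.load_preset`.
Every stage logs a seed derived from the single master seed via
`SeedSequence.spawn`; reports record package version and a config hash,
and repeated runs with one seed are byte-identical.
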