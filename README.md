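# biasdissect

Tools for dissociating **perceptual** from **decisional** biases in
perceptual decision-making, built around the two-task line-length
paradigm: observers categorize target lines as *shorter* or *longer* than
a 350 px reference, or reproduce the target's length, under three bias
manipulations — a Müller-Lyer illusion (arrowhead flankers), a 3:1 base
rate, and an asymmetric 5/1 error payoff. A perceptual bias should move
both choices and reproductions; a decisional bias should move choices
only. The package is aimed at psychophysicists and computational
modellers who want a fully synthetic, seeded replica of this paradigm and
the complete analysis chain over it.

Four layers, each usable on its own:

* **`biasdissect.synth` / `biasdissect.staircase`** — generative
  simulator: weighted up-down staircase calibrated to 75% accuracy,
  five-value target distributions, SDT-style observers (separable
  perceptual shift vs criterion shift) and drift-diffusion observers
  (choices + reaction times).
* **`biasdissect.sdt`** — signal detection statistics with the paradigm's
  conventions: `d' = Z(HR) − Z(FAR)`, `c = ½(Z(HR) + Z(FAR))` (higher `c`
  = more *long* responses), reproduction errors, paired effect sizes,
  participant exclusion rules, and RT-quintile conditional bias
  functions.
* **`biasdissect.bayes`** — JZS paired-t Bayes factors (Cauchy scale
  √2/2) and encompassing-prior ordinal model comparison over named models
  (null / A / C / GG) with equality and order constraints.
* **`biasdissect.ddm`** — Wiener first-passage densities (series
  expansion, analytic across-trial drift variability), a bridge-corrected
  simulator, and a hierarchical Bayesian fit with condition-dependent
  starting point `z` and drift criterion `dc` (stimulus coding: upper
  boundary = *long*), plus Gelman-Rubin diagnostics, posterior predictive
  checks and arrowhead-gradient contrasts.

A `biasdissect` CLI (`simulate`, `analyze`, `sdt`, `cbf`, `bf`,
`ddm-fit`, `ppc`, `report`) drives the end-to-end pipeline from YAML
presets. See `docs/methods.md` for models, priors and numerical choices.

## Worked example

```python
import numpy as np
from biasdissect.synth import make_sdt_cohort, generate_dataset, study_design
from biasdissect.sdt import sdt_table, reproduction_error, long_minus_short
from biasdissect.bayes import jzs_paired_bf

designs = [study_design("muller_lyer", "short"),
           study_design("muller_lyer", "long", block_index=1)]
cohort = make_sdt_cohort(20, "muller_lyer", seed=2)   # staircase-calibrated
trials = generate_dataset(designs, cohort, seed=3)    # 20 x 600 trials

crit = long_minus_short(sdt_table(trials), "criterion")
rep = long_minus_short(reproduction_error(trials), "reproduction_error_px")
print(f"criterion long-short: {crit.mean:.3f} (d = {crit.cohens_d:.2f})")
print(f"reproduction long-short: {rep.mean:.1f} px (d = {rep.cohens_d:.2f})")
print(f"BF10 (reproduction): {jzs_paired_bf(rep.differences):.1f}")
```

prints

```
criterion long-short: 0.235 (d = 0.70)
reproduction long-short: 13.3 px (d = 0.79)
BF10 (reproduction): 18.1
```

i.e. the illusion shifts the decision criterion by ~0.2 z-units *and*
shifts reproductions by ~13 px (≈ twice the generating ±8 px perceptual
shift, attenuated by subject heterogeneity), with strong Bayesian
evidence — whereas a payoff or base-rate
cohort shows a comparable criterion shift but a reproduction difference
near zero. Fitting the drift-diffusion layer to the decision-only
experiments attributes a payoff/base-rate-style bias to the starting
point (bias concentrated in fast responses) and an illusion-style bias to
the drift criterion (bias at all response speeds).

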