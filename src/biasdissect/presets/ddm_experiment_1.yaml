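# Decision-only experiment 1: within-subject Müller-Lyer and payoff,
# reduced penalty asymmetry (2/4), no horizontal jitter, 22 reversals all
# used in the staircase average.
name: ddm_experiment_1
observer_model: ddm
reference_px: 350
jitter_px: null
fixation_ms: [700]
staircase:
  start_step: 20
  n_reversals_total: 22
  n_reversals_used: 22
  target_rate: 0.75
trials_per_cell: 150
base_rate_ratio: 3.0
payoff_penalties: [4, 2]
within_subject: true
groups:
  - bias_source: muller_lyer
    n_subjects: 48
    arrowhead_px: 40
    dc_contrast: 0.35
    z_contrast: -0.03
  - bias_source: payoff
    n_subjects: 48
    dc_contrast: 0.15
    z_contrast: 0.12
ddm_group:
  a: 2.0
  v: 1.0
  t0: 0.3
  sv: 0.2
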