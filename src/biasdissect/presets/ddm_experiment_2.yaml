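# Decision-only experiment 2: between-subjects Müller-Lyer (four arrowhead
# lengths, within-subject) and payoff groups; standard 5/1 penalties.
name: ddm_experiment_2
observer_model: ddm
reference_px: 350
jitter_px: [5, 9]
fixation_ms: [500]
staircase:
  start_step: 20
  n_reversals_total: 25
  n_reversals_used: 20
  target_rate: 0.75
trials_per_cell: 150
base_rate_ratio: 3.0
payoff_penalties: [5, 1]
within_subject: false
groups:
  - bias_source: muller_lyer
    n_subjects: 42
    arrowhead_px: [30, 40, 50, 60]
    dc_contrast: [0.15, 0.22, 0.29, 0.36]
    z_contrast: [-0.02, -0.02, -0.02, -0.02]
  - bias_source: payoff
    n_subjects: 42
    dc_contrast: 0.20
    z_contrast: 0.12
ddm_group:
  a: 2.0
  v: 1.0
  t0: 0.3
  sv: 0.2
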