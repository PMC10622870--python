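# Two-task (categorize/reproduce) bias experiment: three between-subjects
# bias sources, two within-subject bias directions, SDT-style observers.
name: reproduction_experiment
observer_model: sdt
reference_px: 350
jitter_px: [5, 9]
fixation_ms: [600, 700, 800]
reproduction_feedback_threshold_px: 40
staircase:
  start_step: 20
  n_reversals_total: 25
  n_reversals_used: 20
  target_rate: 0.75
trials_per_block: 300
task_mix: 0.5
base_rate_ratio: 3.0
payoff_penalties: [5, 1]
groups:
  - bias_source: muller_lyer
    n_subjects: 46
    arrowhead_px: 40
  - bias_source: base_rate
    n_subjects: 44
  - bias_source: payoff
    n_subjects: 48
observer:
  perceptual_shift_px: 8.0
  perceptual_shift_sd: 8.0
  criterion_shift_px: 10.0
  criterion_shift_sd: 8.0
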