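ability_mean_logit: 0.0
decline_profile:
  '2':
    accuracy_logit_shift: -0.05
    rt_log_shift: 0.04
  '3':
    accuracy_logit_shift: -0.06
    rt_log_shift: 0.05
  '4':
    accuracy_logit_shift: -0.07
    rt_log_shift: 0.06
  '5':
    accuracy_logit_shift: -0.08
    rt_log_shift: 0.07
  '6':
    accuracy_logit_shift: -0.09
    rt_log_shift: 0.08
  '7':
    accuracy_logit_shift: -0.12
    rt_log_shift: 0.1
  '8':
    accuracy_logit_shift: -0.09
    rt_log_shift: 0.08
  '9':
    accuracy_logit_shift: -0.1
    rt_log_shift: 0.09
n_control: 5
n_control_attempts: 4
n_intervention: 15
practice_gain_logit: 0.08
practice_rt_log: -0.025
practice_runs_before_baseline: 3
rt_shift_seconds: 0.2
rt_sigma_log: 0.3
schedule:
- index: 1
  label: Baseline (sitting)
  minutes_from_start: 0.0
  position: sitting
- index: 2
  label: 30 minutes after Trendelenburg positioning
  minutes_from_start: 30
  position: trendelenburg
- index: 3
  label: 60 minutes after Trendelenburg positioning
  minutes_from_start: 60
  position: trendelenburg
- index: 4
  label: 90 minutes after Trendelenburg positioning
  minutes_from_start: 90
  position: trendelenburg
- index: 5
  label: 120 minutes after Trendelenburg positioning
  minutes_from_start: 120
  position: trendelenburg
- index: 6
  label: 150 minutes after Trendelenburg positioning
  minutes_from_start: 150
  position: trendelenburg
- index: 7
  label: Supine (after 180 minutes in the Trendelenburg position)
  minutes_from_start: 180
  position: trendelenburg
- index: 8
  label: 30 minutes after supine positioning
  minutes_from_start: 210.0
  position: supine
- index: 9
  label: Sitting up (60 minutes after supine positioning)
  minutes_from_start: 240.0
  position: sitting
seed: 42
speed_mean_log: 0.0
subject_sd_logit: 0.5
subject_sd_rt_log: 0.12
susceptibility_multiplier: 3.5
susceptible_fraction: 0.3333333333333333
test_specs:
- difficulty_logit: -3.2
  incongruent_fraction: 0.5
  log_rt_offset: -1.05
  n_trials: 30
  nonword_fraction: 0.5
  target_rate: 0.3
  test_id: nback1
- difficulty_logit: -2.31
  incongruent_fraction: 0.5
  log_rt_offset: -0.76
  n_trials: 30
  nonword_fraction: 0.5
  target_rate: 0.3
  test_id: nback2
- difficulty_logit: -1.5
  incongruent_fraction: 0.5
  log_rt_offset: -0.51
  n_trials: 30
  nonword_fraction: 0.5
  target_rate: 0.3
  test_id: nback3
- difficulty_logit: -2.9
  incongruent_fraction: 0.5
  log_rt_offset: -0.6
  n_trials: 30
  nonword_fraction: 0.5
  target_rate: 0.3
  test_id: stroop
- difficulty_logit: -2.7
  incongruent_fraction: 0.5
  log_rt_offset: -0.8
  n_trials: 30
  nonword_fraction: 0.5
  target_rate: 0.3
  test_id: ldt
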