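# Example generator configuration for `restact synth`.
# Omitted fields fall back to the defaults in restact.synth.SynthConfig.
n_subjects_per_group: 5
n_days: 22
seed: 1
rest_min: 2
rest_max: 480
active_alpha: 0.86
active_beta: 0.60
night_suppression: 0.2
cortisol_target_r: 0.72
cortisol_slope: 0.0005
rest_gamma:
  UE: 1.10
  VPA: 1.38
cosinor_truth:
  UE:  {mesor: 160.0, amp24: 120.0, acro24: 2.86, amp12: 50.0, acro12: 3.04}
  VPA: {mesor: 200.0, amp24: 140.0, acro24: 2.88, amp12: 70.0, acro12: 2.84}
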