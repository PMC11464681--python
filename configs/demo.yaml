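# Small end-to-end demo: completes in a few minutes on one CPU.
seed: 0
behavior:
  n_subjects: 24
  n_trials: 120
  em_restarts: 4
fc:
  n_subjects: 24
  n_timepoints: 300
  within_corr: 0.5
  between_corr: 0.1
clustering:
  r: 0.95
  n_clusters: null
association:
  responses: [sigma_vm]
  n_bootstrap: 200
  candidates: [fc_w_N6, fc_b_N3_N5]
linked_demo:
  response: sigma_vm
  enabled: true
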