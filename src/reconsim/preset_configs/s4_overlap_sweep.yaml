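kind: grid
label: s4_overlap_sweep
description: Effect of shock/non-shock pattern overlap on reconsolidation and extinction; values are shared
  active neurons (of 14).
t_values: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
panels:
- name: vehicle
  param: overlap
  values: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
  arm: {}
- name: anisomycin
  param: overlap
  values: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
  arm: {S_reexposure: 0.0}
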