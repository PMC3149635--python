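kind: grid
label: s8_SD_sweeps
description: Sensitivity of reconsolidation and extinction to the S and D factors.
t_values: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
panels:
- name: S_vehicle
  param: S_global
  values: [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
  arm: {}
- name: S_anisomycin
  param: S_training
  values: [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
  arm: {S_reexposure: 0.0}
- name: D_vehicle
  param: D_global
  values: [0.75, 1.0, 1.25, 1.5, 1.75, 2.0]
  arm: {}
- name: D_anisomycin
  param: D_global
  values: [0.75, 1.0, 1.25, 1.5, 1.75, 2.0]
  arm: {S_reexposure: 0.0}
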