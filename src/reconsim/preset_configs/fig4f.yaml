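kind: grid
label: fig4f
description: As fig4e with anisomycin (S=0) during reexposure.
t_values: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
panels:
- name: anisomycin
  param: S_training
  values: [0.6, 0.7, 0.8, 0.9, 0.95, 1.0]
  arm: {S_reexposure: 0.0}
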