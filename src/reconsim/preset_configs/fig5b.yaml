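kind: grid
label: fig5b
description: Freezing after reexposure for each duration and S value during the reexposure session.
t_values: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
panels:
- name: S_reexposure
  param: S_reexposure
  values: [0.0, 0.4, 0.6, 0.7, 0.8, 0.9, 0.95]
  arm: {}
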