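kind: sweep
label: fig3f
description: Freezing after a single reexposure of each duration t=0..10, vehicle vs anisomycin.
t_values: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
arms:
  vehicle: {}
  anisomycin: {S_reexposure: 0.0}
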