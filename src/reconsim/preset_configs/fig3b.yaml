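kind: protocol
label: fig3b
description: Anisomycin during a reexposure session of duration t=1.
arms:
  vehicle:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - &id001 {kind: DECAY}
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 1.0, label: reexposure}
    - {kind: TEST, label: after reexposure}
  anisomycin:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 1.0, label: reexposure, S_override: 0.0}
    - {kind: TEST, label: after reexposure}
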