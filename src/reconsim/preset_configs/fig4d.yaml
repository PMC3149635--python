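kind: protocol
label: fig4d
description: 'Long (t=10) reexposure after strong training (S=0.95): extinction fails in controls and
  anisomycin causes reconsolidation blockade instead.'
arms:
  vehicle:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - &id001 {kind: DECAY}
    - {kind: TRAIN, pattern_id: 2, S_override: 0.95, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 10.0, label: reexposure}
    - {kind: TEST, label: after reexposure}
  anisomycin:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, S_override: 0.95, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 10.0, label: reexposure, S_override: 0.0}
    - {kind: TEST, label: after reexposure}
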