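kind: protocol
label: fig5a
description: 'Memory-enhancing drug (S=0.95) during reexposure: slight reinforcement at intermediate t,
  enhanced extinction at long t.'
arms:
  vehicle_t4:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - &id001 {kind: DECAY}
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 4.0, label: reexposure}
    - {kind: TEST, label: after reexposure}
  enhanced_t4:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 4.0, label: reexposure, S_override: 0.95}
    - {kind: TEST, label: after reexposure}
  vehicle_t8:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 8.0, label: reexposure}
    - {kind: TEST, label: after reexposure}
  enhanced_t8:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 8.0, label: reexposure, S_override: 0.95}
    - {kind: TEST, label: after reexposure}
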