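kind: protocol
label: s7_enhanced_D
description: Enhanced degradation (D=1.5) during reexposure impairs reconsolidation (single t=7.5 session)
  and accelerates multi-session extinction.
arms:
  single_vehicle:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - &id001 {kind: DECAY}
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 7.5, label: reexposure}
    - {kind: TEST, label: after reexposure}
  single_enhanced:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 7.5, label: reexposure, D_override: 1.5}
    - {kind: TEST, label: after reexposure}
  multi_vehicle:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 6.0, label: reexposure 1}
    - {kind: TEST, label: after session 1}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 2}
    - {kind: TEST, label: after session 2}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 3}
    - {kind: TEST, label: after session 3}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 4}
    - {kind: TEST, label: after session 4}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 5}
    - {kind: TEST, label: after session 5}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 6}
    - {kind: TEST, label: after session 6}
  multi_enhanced:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 6.0, label: reexposure 1, D_override: 1.5}
    - {kind: TEST, label: after session 1}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 2, D_override: 1.5}
    - {kind: TEST, label: after session 2}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 3, D_override: 1.5}
    - {kind: TEST, label: after session 3}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 4, D_override: 1.5}
    - {kind: TEST, label: after session 4}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 5, D_override: 1.5}
    - {kind: TEST, label: after session 5}
    - {kind: REEXPOSE, t: 6.0, label: reexposure 6, D_override: 1.5}
    - {kind: TEST, label: after session 6}
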