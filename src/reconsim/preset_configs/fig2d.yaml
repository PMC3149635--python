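kind: protocol
label: fig2d
description: Extinction over 6 massed reexposure sessions of intermediate duration (t=6); decay applied
  only before the first session.
arms:
  standard:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - &id001 {kind: DECAY}
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
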