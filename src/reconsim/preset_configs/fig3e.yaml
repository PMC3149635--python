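kind: protocol
label: fig3e
description: 'Anisomycin paired with an unrelated-context session instead of contextual reexposure: no
  amnestic effect on the shock memory.'
arms:
  vehicle:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - &id001 {kind: DECAY}
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: TRAIN_UNRELATED, label: unrelated-context session}
    - {kind: TEST, label: after unrelated session}
  anisomycin:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: TRAIN_UNRELATED, label: unrelated-context session, S_override: 0.0}
    - {kind: TEST, label: after unrelated session}
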