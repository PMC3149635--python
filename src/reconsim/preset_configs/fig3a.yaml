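kind: protocol
label: fig3a
description: Anisomycin at initial learning blocks formation of the shock memory.
arms:
  vehicle:
    sessions:
    - {kind: TRAIN, pattern_id: 1}
    - {kind: TEST, label: before}
    - &id001 {kind: DECAY}
    - {kind: TRAIN, pattern_id: 2}
    - {kind: TEST, label: after learning}
  anisomycin:
    sessions:
    - {kind: TRAIN, pattern_id: 1}
    - {kind: TEST, label: before}
    - *id001
    - {kind: TRAIN, pattern_id: 2, S_override: 0.0}
    - {kind: TEST, label: after learning}
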