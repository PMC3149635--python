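kind: protocol
label: fig2c
description: 'Fear conditioning and extinction: freezing after learning memory 1, after learning memory
  2, and after a single long (t=10) extinction session.'
arms:
  standard:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - {kind: TEST, label: after memory 1}
    - &id001 {kind: DECAY}
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after memory 2}
    - *id001
    - {kind: REEXPOSE, t: 10.0, label: extinction}
    - {kind: TEST, label: after extinction}
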