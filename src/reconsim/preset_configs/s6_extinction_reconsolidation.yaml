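kind: protocol
label: s6_extinction_reconsolidation
description: 'Reconsolidation blockade targets whichever memory is retrieved: the fear memory before extinction,
  the extinction memory after it.'
arms:
  fear_vehicle:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - &id001 {kind: DECAY}
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 5.0, label: reexposure}
    - {kind: TEST, label: after reexposure}
  fear_anisomycin:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - {kind: TEST, label: after training}
    - *id001
    - {kind: REEXPOSE, t: 5.0, label: reexposure, S_override: 0.0}
    - {kind: TEST, label: after reexposure}
  extinction_vehicle:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - *id001
    - {kind: REEXPOSE, t: 10.0, label: extinction}
    - {kind: TEST, label: after extinction}
    - *id001
    - {kind: REEXPOSE, t: 5.0, label: reminder reexposure}
    - {kind: TEST, label: final}
  extinction_anisomycin:
    sessions:
    - {kind: TRAIN, pattern_id: 1, label: train unrelated}
    - *id001
    - {kind: TRAIN, pattern_id: 2, label: train shock}
    - *id001
    - {kind: REEXPOSE, t: 10.0, label: extinction}
    - {kind: TEST, label: after extinction}
    - *id001
    - {kind: REEXPOSE, t: 5.0, label: reminder reexposure, S_override: 0.0}
    - {kind: TEST, label: final}
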