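kind: retrieval
label: fig2b
description: 'Attractor retrieval after learning memories 1 and 2: random initialization without a cue,
  or with a weak 4-neuron cue for either pattern.'
n_sets: 10
strength: 0.1
cues:
  no_cue: {pattern_id: null}
  cue_pattern1: {pattern_id: 1, n_cue: 4}
  cue_pattern2: {pattern_id: 2, n_cue: 4}
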