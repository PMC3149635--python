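# reconsim

Attractor-network simulation of memory **reconsolidation** and
**extinction** in contextual fear conditioning.

A long-standing puzzle in behavioral neuroscience is that the same amnestic
drug (e.g. the protein-synthesis inhibitor anisomycin), given after
nonreinforced reexposure to a conditioning context, can either erase the
fear memory (reconsolidation blockade) or preserve it (extinction
blockade), depending on how long the reexposure lasts.  `reconsim`
implements a recurrent network model in which both outcomes — plus simple
retrieval — emerge from a single pair of plasticity rules, and provides the
protocol machinery (training, reexposure, drug conditions, freezing
readout), energy-landscape visualization and storage-capacity estimation
around it.  It is aimed at computational-neuroscience users who want to
rerun, probe or extend the model from Python or the shell.

## The model

A fully connected network of `N = 100` rate units with activations
`u_i ∈ [0, 1]` relaxes under

    τ du_i/dt = −u_i + ½ (1 + tanh( Σ_j w_ij u_j + I_i ))

where `w_ij` is the weight of the connection j→i (`|w| ≤ s₀`, no
self-connections) and `I_i ∈ [−5, 5]` are cue currents.  Memories are
binary patterns (14 active neurons; the shock and non-shock patterns share
4 *context* neurons) stored as attractors.  After each behavioral session
the steady state `u` updates the weights by

    Δw = HLP + MID,   HLP_ji = S · u_i (2u_j − 1),   MID_ji = D · u_i (Î_j − u_j)

with `Î` the cue normalized to `[0, 1]`.  `HLP` is Hebbian strengthening
(scaled by the synthesis factor `S`; anisomycin ⇒ `S = 0`), `MID` degrades
exactly the connections responsible for disagreement between the cue and
the retrieved attractor (scaled by the degradation factor `D`; proteasome
blockade ⇒ `D = 0`).  Between sessions, weights decay once by
`w ← (1 − γ) w`.  During nonreinforced reexposure of duration
`t ∈ [0, 10]` the cue is a logistic mix
`I(t) = (1 − f(t))·cue_shock + f(t)·cue_nonshock`, so short sessions
re-present the fear memory and long sessions the competing "no shock"
memory.  At test, a weak cue (`I = 0.1`) on the 4 context neurons drives
retrieval; retrieving the shock attractor maps to 90% freezing, anything
else to 10%, averaged over 100 replicates with random initial activations
`u₀ ~ U[0, 0.1]`.

Defaults: `τ = 1, γ = 0.15, s₀ = 1, S = 0.8, D = 1.25`.

## Worked example

Sweep the reexposure duration under vehicle and under anisomycin
(`examples/02_reconsolidation_vs_extinction.py`):

```python
from reconsim import reexposure_sweep, extinction_onset

curve = reexposure_sweep(
    range(11),
    {"vehicle": {}, "anisomycin": {"S_reexposure": 0.0}},
    n_replicates=100, seed=0,
)
```

prints (mean freezing %, 100 replicates per cell):

```
  t   vehicle  anisomycin
  0      90.0        86.0
  3      90.0        75.6
  4      90.0        44.4
  6      90.0        10.0
  8      20.4        86.8
 10      10.0        88.4
```

Three regimes appear along the anisomycin column: at `t ≤ 2` the drug does
nothing (simple retrieval — almost no mismatch to degrade), at
`t = 4..7` it collapses freezing to baseline (reconsolidation blockade:
degradation unopposed by blocked Hebbian re-strengthening), and from
`t = 8` — exactly where vehicle controls start to extinguish
(`extinction_onset(curve, arm="vehicle") → 8`) — it *preserves* fear by
blocking the learning of the extinction memory.

Other entry points: `run_preset("fig6a")` and the other 20+ named presets
(YAML files under `reconsim/preset_configs/`), `grid_sweep` for
duration × parameter color plots, `energy_landscape`/`mda_projection` for
basin visualization, `capacity_curve` for storage capacity.  The same
functionality is exposed on the command line:

```bash
reconsim run fig3f --seed 0 --out results/
reconsim sweep --param S_training --values 0.6,0.8,0.95 --out results/
reconsim landscape --stage fig2a --out results/
reconsim capacity --sizes 100,200,300 --out results/
```

Each command writes tidy CSV + JSON plus a manifest (config, seeds,
version, timing) from which the run can be replayed.

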