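# Methods

## Model

The simulator is a continuous-activation autoassociative network of the
Cohen–Grossberg/Hopfield family, intended as a minimal stand-in for a
hippocampal storage network (CA3-like recurrent collaterals receiving
cortical cue input).  Activations are bounded in `[0, 1]` by the gain
`g(x) = ½(1 + tanh x)`, so `u_i` reads directly as a normalized firing
rate; compared with the classical ±1 formulation this removes symmetric
connectivity, silent–silent strengthening and mirror attractors.  The flow

    τ du/dt = −u + g(W u + I)

is integrated by forward Euler with `dt = 0.1 τ`.  Since each step forms a
convex combination `(1 − dt/τ) u + (dt/τ) g`, activations stay in `[0, 1]`
exactly at every step.  Steady state is declared when
`max_i |du_i/dt| < 10⁻⁶` per unit time (a max-norm criterion), with a time
cap of `100 τ`; halving `dt` moves the relaxed state by less than 10× the
tolerance on all protocol matrices, which is the integrator's consistency
guard.  Self-connections are forced to zero after every update (standard
autapse-free convention; the rules below would otherwise self-reinforce
active units).

### Plasticity

Both weight-change terms are computed once per session from the steady
state reached under that session's cue — plastic changes are treated as
consolidating in the post-session period — and applied with truncation at
`±s₀`:

* Hebbian term `HLP_ji = S · u_i (2 u_j − 1)`: `+S` between coactive
  units, `−S` from an active to a silent unit (which, because weights may
  be negative, builds inhibition), nothing from silent units.  The form is
  the minimal bilinear interpolation of those three discrete cases.
* Mismatch-induced degradation `MID_ji = D · u_i · m_j` with
  `m = Î − u`, where `Î = (I + I_max) / 2 I_max` maps cue currents onto
  the activation scale.  Units sort into four categories by (cue, state):
  AA, SS (agreement, `m ≈ 0`), AS (cue-excited but suppressed, `m = +1`)
  and SA (cue-suppressed but active, `m = −1`).  Degradation weakens
  precisely the inbound weights that hold AS units down and SA units up.
  During initial learning the steady state equals the (normalized) cue, so
  `MID ≡ 0` — degradation is engaged only by retrieval that contradicts
  the current cue.  For partially active units the same bilinear form
  interpolates smoothly; only the binary cases are sharply constrained,
  and an exhaustive 2×2×2 oracle over `(u_pre, u_post, Î_post)` pins both
  rules in the test suite.

Drugs are session-scoped overrides of the two scalars: protein-synthesis
inhibition `S = 0`, plasticity enhancers `S > 0.8`, degradation blockade
`D = 0`.

### Behavioral protocols

Three deterministic binary patterns over 100 neurons (14 active each):
pattern 1 (unrelated, disjoint), pattern 2 (shock = 4 context + 10 danger
neurons), pattern 3 (non-shock = same 4 context + 10 safety neurons).
Fixed index blocks, not random draws: replicate variability should come
only from initial conditions, as in the original study conditions.
Training presents the full pattern at `±5`; nonreinforced reexposure of
duration `t` presents the logistic mix of the shock and non-shock training
cues with midpoint 5 and slope 1 (any monotone `[0,1]` ramp gives the same
regime structure, shifted along `t`); retrieval tests present `0.1` on the
context neurons only.  Tests never update weights.  Freezing is a
deterministic 90/10 function of the classified attractor (Pearson
`r > 0.7` against the stored binary patterns, ties to the lowest id,
`NONE` for zero-variance states), so the reported mean ± SEM over 100
replicates reflects retrieval stochasticity alone.

**Inter-session decay.**  `γ(t)` is implemented as a discrete event
`w ← (1 − γ) w` standing for the interval between sessions held on
different days: one event between the two training sessions and one before
a (first) reexposure session.  Massed multi-session extinction applies it
only before the first of the six sessions.  This convention is load-bearing:
it makes the most recently reinforced memory the strongest, which is what
lets the 4-neuron, 0.1-strength test cue retrieve the shock attractor near-
deterministically after training.  With all traces at equal strength the
weak cue biases the basin competition only marginally (the early transient,
in which all units rise toward `g(0) = 0.5`, washes out most of the cue's
head start).  This is the package's protocol convention, chosen because it
reproduces the full drug × duration phenomenology; see Limitations for the
two figure-level claims it does not reproduce.

### Energy analysis

The landscape energy is the quadratic form `E(u) = −½ uᵀ W u`, optionally
minus `Iᵀu` for cued landscapes (landscapes of the resting network are the
default).  Because `W` is asymmetric and the gain has a 0.5 baseline, the
flow is not a gradient descent of `E`: along a relaxation from
`u₀ ~ U[0, 0.1]`, `E` rises for roughly half a time constant while the
state leaves the near-uniform regime, and is strictly non-increasing
afterwards on every protocol matrix checked (tolerance 10⁻⁸ per step; the
descent property in the test suite skips the first `τ`).  Final states are
energy minima well below the median random sparse state.

For visualization, states are projected onto the `P − 1 = 2` dimensional
eigenspace of the between-pattern scatter
`S_b = Σ_c (μ_c − μ)(μ_c − μ)ᵀ` (multiple discriminant analysis; rows of
the basis orthonormal, signs fixed by first-nonzero-positive).  The
landscape grid assigns each of 50×50 cells the mean energy of its
k = 20 nearest projected samples, from a pool of 2000 states, half uniform
random 14-active binary states (ridges) and half relaxed states from
random initializations (basin floors); the sampling scheme and smoothing
constants are package choices, exposed as arguments.  Cells containing no
sample are flagged empty rather than zero.

### Storage capacity

Capacity is measured operationally: store `P` random 14-active patterns by
sequential Hebbian updates, then run retrieval trials — a cue on 4 random
active neurons of a random target, random `u₀` — and score success as
Pearson `r > 0.7` with the target.  Two hundred trials per (N, P) point,
with patterns redrawn every 20 trials so the estimate averages over
pattern realizations.  Retrieval cues for capacity are presented at full
training strength (`I = 5`): with the weak behavioral strength (0.1) the
cue cannot steer the competition between equally strong random attractors
and success collapses to `1/P` regardless of load, which measures cue
sensitivity rather than storage.  Capacity rises with network size and
with pattern sparseness (7-active patterns, 2-neuron cues), and the
3-pattern load of the behavioral protocols retrieves essentially perfectly
at `N = 100`.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `N` | 100 | network size; all behavioral results use it |
| `τ` | 1 | time unit of the rate dynamics |
| `dt` | 0.1 τ | Euler step; convexity keeps states in `[0,1]` |
| `tol` | 10⁻⁶/τ | steady-state max-norm criterion |
| `S` | 0.8 | Hebbian synthesis factor (training and vehicle reexposure) |
| `D` | 1.25 | mismatch degradation factor |
| `γ` | 0.15 | per-interval decay fraction |
| `s₀` | 1 | weight saturation bound (truncation) |
| `I_max` | 5 | training-cue magnitude |
| test strength | 0.1 | weak context cue at retrieval tests |
| `t` range | 0–10 | reexposure duration; logistic mix midpoint 5, slope 1 |
| `r` threshold | 0.7 | retrieval classification |
| replicates | 100 | per condition; `u₀ ~ U[0, 0.1]` i.i.d. |

## What the simulations do and do not emulate

All inputs are generated internally; there is no external data.  The
synthetic protocols emulate one-trial contextual fear conditioning with a
single reexposure knob `t` standing for session duration (equivalently,
learning/reexposure dissimilarity).  They do not emulate within-session
dynamics of the animal's percept (the cue mix is an end-of-session
summary), reinforced reexposure, spiking or STDP-level mechanisms, or
biochemistry beyond the two scalars `S` and `D`.  Passing tests therefore
certify the network-level logic — which retrieval/plasticity regime occurs
when — not quantitative correspondence to any particular behavioral
dataset.

## Known limitations

* **Regime transitions are sharp.**  Retrieval during reexposure is almost
  deterministic given `t`, so freezing means jump between ~90 and ~10 over
  one duration unit (e.g. vehicle: 90 at `t = 7`, ~20 at `t = 8`).
  Behavioral data (and the smoother curves the model family is known for)
  show more graded transitions; in this integrator the initial-condition
  noise rarely flips the session-level outcome away from the boundary.
  Consequently, at `t = 8` an `S = 0.95` enhancer deepens extinction only
  from ~19% to 10% freezing — the direction holds but the margin is small,
  because controls at `t = 8` have already largely extinguished.
* **Weak-cue bias at equal trace strengths.**  With two attractors of
  identical weight strength, a 0.1-strength 4-neuron cue shifts retrieval
  probability only a few percent (see the decay note above).  Retrieval
  preference demonstrations at equal strengths are therefore much weaker
  than the near-deterministic cued retrieval the protocols show, and in
  the unrelated-context control the vehicle arm — which re-strengthens the
  unrelated memory — ends up retrieving that memory at test (low
  freezing); the drug arm's claim (no amnesia for the shock memory without
  contextual reexposure) is unaffected.
* **Classification ties.**  Mixed steady states equally correlated with
  the shock and non-shock patterns classify as shock (lowest id), which
  can mask partial degradation in extreme-`D` conditions.
* Energy descent is an empirical property of the trained matrices, not a
  theorem: the weights are asymmetric and no Lyapunov function is claimed.
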