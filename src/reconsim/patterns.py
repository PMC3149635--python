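"""Memory patterns and cue construction for the fear-conditioning task.

Three binary patterns over ``N`` neurons stand in for the memories an animal
can form in a contextual fear-conditioning experiment:

* pattern 1 — an **unrelated** memory, sharing no neurons with the others;
* pattern 2 — the **shock** memory: context neurons plus "danger" neurons;
* pattern 3 — the **non-shock** (extinction) memory: the same context
  neurons plus "safety" neurons.

Patterns 2 and 3 overlap exactly on the context neurons, which is what makes
the context cue ambiguous between them.  Cues are current vectors: training
cues drive the full pattern at ``±I_max``, retrieval-test cues weakly excite
only the context neurons and let the attractor dynamics complete the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import I_MAX

__all__ = [
    "UNRELATED",
    "SHOCK",
    "NONSHOCK",
    "PatternSet",
    "build_default_patterns",
    "build_overlap_patterns",
    "training_cue",
    "test_cue",
]

UNRELATED = 1
SHOCK = 2
NONSHOCK = 3


@dataclass(frozen=True)
class PatternSet:
    """Stored binary memory patterns with their labelled index sets."""

    n_neurons: int
    active_size: int
    n_context: int
    vectors: dict[int, np.ndarray] = field(repr=False)
    context_idx: np.ndarray
    shock_idx: np.ndarray  # active in pattern 2 only
    nonshock_idx: np.ndarray  # active in pattern 3 only
    unrelated_idx: np.ndarray  # active in pattern 1

    @property
    def ids(self) -> list[int]:
        return sorted(self.vectors)

    def vector(self, pattern_id: int) -> np.ndarray:
        """Binary (0/1) activity vector of a stored pattern."""
        return self.vectors[pattern_id]

    def overlap(self, a: int, b: int) -> int:
        """Number of neurons active in both patterns ``a`` and ``b``."""
        return int(np.sum(self.vectors[a] * self.vectors[b]))


def _as_vector(n_neurons: int, idx: np.ndarray) -> np.ndarray:
    v = np.zeros(n_neurons)
    v[idx] = 1.0
    return v


def build_overlap_patterns(
    n_shared: int,
    n_neurons: int = 100,
    active_size: int = 14,
    n_context: int = 4,
) -> PatternSet:
    """Pattern set in which memories 2 and 3 share ``n_shared`` active neurons.

    The layout is deterministic index blocks: pattern 1 first, then the
    block shared between patterns 2 and 3, then each pattern's private
    block.  The context (test-cue) neurons are the first ``n_context``
    active neurons of pattern 2, taken from the shared block first, so at
    the default ``n_shared = n_context`` they are exactly the shared
    neurons.  Used to probe how pattern overlap gates extinction.
    """
    if not 0 <= n_shared <= active_size:
        raise ValueError(
            f"n_shared must be in [0, {active_size}], got {n_shared}"
        )
    n_private = active_size - n_shared
    needed = active_size + n_shared + 2 * n_private
    if needed > n_neurons:
        raise ValueError(
            f"pattern layout needs {needed} neurons but the network has {n_neurons}"
        )
    if n_context > active_size:
        raise ValueError(
            f"n_context ({n_context}) cannot exceed active_size ({active_size})"
        )

    p1 = np.arange(0, active_size)
    shared = np.arange(active_size, active_size + n_shared)
    uniq2 = np.arange(shared[-1] + 1 if n_shared else active_size,
                      active_size + n_shared + n_private)
    uniq3 = np.arange(active_size + n_shared + n_private, needed)

    p2 = np.concatenate([shared, uniq2]).astype(int)
    p3 = np.concatenate([shared, uniq3]).astype(int)

    # context neurons: shared ones first, topped up from pattern 2's private block
    if n_shared >= n_context:
        context = shared[:n_context]
    else:
        context = np.concatenate([shared, uniq2[: n_context - n_shared]])

    vectors = {
        UNRELATED: _as_vector(n_neurons, p1),
        SHOCK: _as_vector(n_neurons, p2),
        NONSHOCK: _as_vector(n_neurons, p3),
    }
    return PatternSet(
        n_neurons=n_neurons,
        active_size=active_size,
        n_context=n_context,
        vectors=vectors,
        context_idx=context.astype(int),
        shock_idx=uniq2.astype(int),
        nonshock_idx=uniq3.astype(int),
        unrelated_idx=p1.astype(int),
    )


def build_default_patterns(
    n_neurons: int = 100,
    active_size: int = 14,
    n_context: int = 4,
) -> PatternSet:
    """Default pattern set: 14-neuron patterns, 4 shared context neurons.

    Memories 2 and 3 overlap only on the context neurons
    (``n_context / active_size`` = 4/14 ≈ 29% of active neurons), and
    memory 1 is orthogonal to both.
    """
    return build_overlap_patterns(
        n_shared=n_context,
        n_neurons=n_neurons,
        active_size=active_size,
        n_context=n_context,
    )


def training_cue(pattern: np.ndarray, I_max: float = I_MAX) -> np.ndarray:
    """Full-strength training cue: ``+I_max`` on active neurons, ``-I_max`` elsewhere.

    Clamps the whole network to the pattern, so the steady state during a
    training session is the pattern itself.
    """
    pattern = np.asarray(pattern, dtype=float)
    return np.where(pattern > 0.5, I_max, -I_max)


def test_cue(patterns: PatternSet, strength: float = 0.1) -> np.ndarray:
    """Weak retrieval cue: ``strength`` on the context neurons, 0 elsewhere.

    Retrieval is then genuine pattern completion — the cue only biases the
    competition between stored attractors.
    """
    if strength < 0:
        raise ValueError(f"strength must be non-negative, got {strength}")
    I = np.zeros(patterns.n_neurons)
    I[patterns.context_idx] = strength
    return I
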