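"""Synaptic plasticity: Hebbian strengthening and mismatch-induced degradation.

Two independent processes change the weight matrix after each session, both
computed from the steady state ``u`` the network reached during the session:

* **HLP** (Hebbian learning plasticity) — connections from an active unit to
  an active unit strengthen by ``+S``, from an active unit to a silent unit
  weaken by ``-S``, and connections from silent units are untouched.  ``S``
  lumps the biochemical requirements of Hebbian plasticity (protein
  synthesis among them); protein-synthesis inhibitors are modelled as
  ``S = 0``.

* **MID** (mismatch-induced degradation) — acts only where the normalized
  cue and the retrieved attractor disagree.  With mismatch vector
  ``m = i_hat - u``, the connection from an active unit ``i`` to a unit
  ``j`` changes by ``D * m_j``: degradation weakens exactly the weights that
  force the network away from what the cue says.  ``D`` lumps the
  degradation machinery (e.g. the ubiquitin-proteasome system); degradation
  blockers are modelled as ``D = 0``.

Weight entries saturate at ``±s0`` by truncation, and a discrete decay event
``w <- (1 - gamma) w`` models slow time-dependent weakening between distant
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import I_MAX

__all__ = [
    "PlasticityParams",
    "normalize_cue",
    "hlp_matrix",
    "mismatch_vector",
    "mid_matrix",
    "update_weights",
    "apply_decay",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Plasticity parameters (defaults: S=0.8, D=1.25, gamma=0.15, s0=1).

    S : Hebbian synthesis factor, >= 0.
    D : mismatch degradation factor, >= 0.
    gamma : fractional decay per inter-session decay event, in [0, 1).
    s0 : saturation bound on |w|, > 0.
    """

    S: float = 0.8
    D: float = 1.25
    gamma: float = 0.15
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError(f"S must be non-negative, got {self.S}")
        if self.D < 0:
            raise ValueError(f"D must be non-negative, got {self.D}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.s0 <= 0:
            raise ValueError(f"s0 must be positive, got {self.s0}")


def normalize_cue(I: np.ndarray, I_max: float = I_MAX) -> np.ndarray:
    """Affine map of cue currents from ``[-I_max, +I_max]`` onto ``[0, 1]``.

    ``i_hat = (I + I_max) / (2 I_max)``, so a maximally excitatory current
    maps to 1, a maximally inhibitory one to 0 and zero current to 0.5.
    The normalized cue lives on the same scale as the activations and is
    what the mismatch vector compares against.
    """
    if I_max <= 0:
        raise ValueError(f"I_max must be positive, got {I_max}")
    I = np.asarray(I, dtype=float)
    return (I + I_max) / (2.0 * I_max)


def hlp_matrix(u: np.ndarray, S: float) -> np.ndarray:
    """Hebbian weight-change matrix ``HLP[j, i] = S * u_i * (2 u_j - 1)``.

    For binary activities this reproduces the three discrete cases: +S for
    active->active, -S for active->silent, 0 from a silent presynaptic
    unit; intermediate activities interpolate continuously.
    """
    u = np.asarray(u, dtype=float)
    return S * np.outer(2.0 * u - 1.0, u)


def mismatch_vector(i_hat: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Mismatch ``m = i_hat - u`` between the normalized cue and the attractor.

    An entry of +1 marks a unit the cue excites but the network suppressed;
    -1 marks a unit the cue suppresses but the network activated.  All-zero
    when the retrieved state agrees with the cue (e.g. initial learning).
    """
    i_hat = np.asarray(i_hat, dtype=float)
    u = np.asarray(u, dtype=float)
    if i_hat.shape != u.shape:
        raise ValueError(
            f"i_hat shape {i_hat.shape} does not match activity shape {u.shape}"
        )
    return i_hat - u


def mid_matrix(u: np.ndarray, m: np.ndarray, D: float) -> np.ndarray:
    """Degradation matrix ``MID[j, i] = D * u_i * m_j``.

    Only connections leaving active units change, and only towards units in
    disagreement with the cue: +D towards cue-excited-but-suppressed units
    (weakening their inhibition), -D towards cue-suppressed-but-active units.
    Identically zero when ``m = 0``.
    """
    u = np.asarray(u, dtype=float)
    m = np.asarray(m, dtype=float)
    if u.shape != m.shape:
        raise ValueError(f"u shape {u.shape} does not match m shape {m.shape}")
    return D * np.outer(m, u)


def update_weights(
    w: np.ndarray,
    hlp: np.ndarray,
    mid: np.ndarray,
    s0: float = 1.0,
) -> np.ndarray:
    """One post-session weight update: ``w' = clip(w + HLP + MID, -s0, +s0)``.

    Saturation by truncation keeps any one memory from dominating the
    matrix; the diagonal is forced to zero (no self-connections).
    """
    w = np.asarray(w, dtype=float)
    if w.shape != hlp.shape or w.shape != mid.shape:
        raise ValueError(
            f"shape mismatch: w {w.shape}, hlp {np.shape(hlp)}, mid {np.shape(mid)}"
        )
    out = np.clip(w + hlp + mid, -s0, s0)
    np.fill_diagonal(out, 0.0)
    return out


def apply_decay(w: np.ndarray, gamma: float) -> np.ndarray:
    """Discrete inter-session decay event ``w' = (1 - gamma) * w``."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    return (1.0 - gamma) * np.asarray(w, dtype=float)
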