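"""Relaxation dynamics of the continuous-activation attractor network.

The network is a fully connected recurrent net of ``N`` rate units whose
activations ``u_i`` live in ``[0, 1]``.  Given a weight matrix ``w`` (entry
``w[j, i]`` is the connection from neuron ``i`` to neuron ``j``) and a vector
of cue currents ``I``, the state evolves by

    tau * du_i/dt = -u_i + 1/2 * (1 + tanh( sum_j w_ij u_j + I_i ))

so every unit decays towards 0 while being driven by its recurrent input and
its cue current through a sigmoidal gain bounded in ``(0, 1)``.  Memories are
stored as fixed points (attractors) of this flow; retrieval means relaxing
from some initial condition until the state stops moving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DynamicsParams",
    "activation_drive",
    "relax",
    "classify_attractor",
]

#: Hard bound on cue currents (units of synaptic drive).
I_MAX = 5.0


@dataclass(frozen=True)
class DynamicsParams:
    """Integration parameters for :func:`relax`.

    Parameters
    ----------
    tau
        Neural time constant (sets the relaxation timescale; default 1).
    dt
        Forward-Euler step.  Must satisfy ``dt < tau`` so each step is a
        convex combination of the previous state and the bounded drive,
        which keeps activations inside ``[0, 1]`` exactly.
    tol
        Steady-state tolerance on ``max_i |du_i/dt|``.
    t_max_relax
        Cap on integrated time; relaxation stops (flagged unconverged) if
        the tolerance has not been met by then.
    """

    tau: float = 1.0
    dt: float = 0.1
    tol: float = 1e-6
    t_max_relax: float = 100.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.dt >= self.tau:
            raise ValueError(f"dt ({self.dt}) must be smaller than tau ({self.tau})")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")


def _check_lengths(n: int, **named: np.ndarray) -> None:
    for name, vec in named.items():
        if vec.shape != (n,):
            raise ValueError(
                f"{name} has shape {vec.shape}, expected ({n},) to match the weight matrix"
            )


def activation_drive(w: np.ndarray, u: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Sigmoidal drive ``g_i = 1/2 (1 + tanh(sum_j w_ij u_j + I_i))``.

    Every entry is strictly inside ``(0, 1)``; this is the steady-state
    activation each unit is pulled towards.
    """
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    I = np.asarray(I, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"w must be a square matrix, got shape {w.shape}")
    _check_lengths(w.shape[0], u=u, I=I)
    return 0.5 * (1.0 + np.tanh(w @ u + I))


def relax(
    w: np.ndarray,
    I: np.ndarray,
    u0: np.ndarray,
    params: DynamicsParams | None = None,
) -> tuple[np.ndarray, bool]:
    """Integrate the network to its steady state under a fixed cue.

    Forward-Euler integration of ``tau du/dt = -u + g(w, u, I)`` from ``u0``
    until ``max_i |du_i/dt| < tol`` or ``t_max_relax`` is reached.

    Returns
    -------
    (u, converged)
        The final activity vector (entries in ``[0, 1]``) and whether the
        steady-state tolerance was met before the time cap.
    """
    if params is None:
        params = DynamicsParams()
    w = np.asarray(w, dtype=float)
    u = np.array(u0, dtype=float)
    I = np.asarray(I, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"w must be a square matrix, got shape {w.shape}")
    _check_lengths(w.shape[0], u0=u, I=I)
    if u.min() < 0.0 or u.max() > 1.0:
        raise ValueError("u0 entries must lie in [0, 1]")

    step = params.dt / params.tau
    n_steps = int(np.ceil(params.t_max_relax / params.dt))
    converged = False
    for _ in range(n_steps):
        g = 0.5 * (1.0 + np.tanh(w @ u + I))
        du = g - u  # tau * du/dt
        if not np.all(np.isfinite(du)):
            raise FloatingPointError(
                "non-finite values during relaxation; weights or currents are unstable"
            )
        u += step * du
        if np.abs(du).max() < params.tol * params.tau:
            converged = True
            break
    # Euler with dt < tau keeps u in [0, 1] exactly; clip only guards rounding.
    np.clip(u, 0.0, 1.0, out=u)
    return u, converged


def classify_attractor(
    u: np.ndarray,
    patterns: "PatternSet",  # noqa: F821 - forward ref to patterns module
    r_threshold: float = 0.7,
) -> int | None:
    """Identify which stored pattern (if any) the state ``u`` has retrieved.

    Computes the Pearson correlation between ``u`` and each stored binary
    pattern vector and returns the id of the best-matching pattern if its
    correlation exceeds ``r_threshold``; otherwise ``None``.  Ties go to the
    lowest pattern id.  A constant (zero-variance) activity vector has no
    defined correlation and classifies as ``None``.
    """
    if not 0.0 < r_threshold <= 1.0:
        raise ValueError(f"r_threshold must be in (0, 1], got {r_threshold}")
    u = np.asarray(u, dtype=float)
    if np.std(u) == 0.0:
        return None
    best_id: int | None = None
    best_r = -np.inf
    for pid in sorted(patterns.ids):
        vec = patterns.vector(pid).astype(float)
        if np.std(vec) == 0.0:
            continue
        r = float(np.corrcoef(u, vec)[0, 1])
        if r > best_r:
            best_r = r
            best_id = pid
    if best_id is not None and best_r > r_threshold:
        return best_id
    return None
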