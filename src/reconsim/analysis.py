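"""Energy landscapes, low-dimensional projection and storage capacity.

Stored memories are minima of the network's energy function.  To see their
basins of attraction, high-dimensional network states are projected onto
the plane spanned by the stored patterns (multiple discriminant analysis of
the between-pattern scatter), and the mean energy of sampled states is
mapped over that plane.  Storage capacity is estimated the operational way:
store increasing numbers of random patterns, probe retrieval with partial
cues, and count the fraction of successful completions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dynamics import DynamicsParams, relax
from .patterns import PatternSet, training_cue
from .plasticity import hlp_matrix, update_weights

__all__ = [
    "energy",
    "relaxation_energy_profile",
    "Projection",
    "mda_projection",
    "LandscapeGrid",
    "energy_landscape",
    "CapacityCurve",
    "capacity_curve",
]


def energy(w: np.ndarray, u: np.ndarray, I: np.ndarray | None = None) -> float:
    """Quadratic (Lyapunov-style) energy ``E = -1/2 sum_ij w_ij u_i u_j``.

    With ``I`` given, the cue term ``- sum_i I_i u_i`` is included.  Stored
    attractors sit at low energy; the landscape over state space visualizes
    their basins.  The default (no cue) matches how landscapes of the
    resting network are drawn.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != (u.size, u.size):
        raise ValueError(f"w shape {w.shape} does not match state length {u.size}")
    e = -0.5 * float(u @ w @ u)
    if I is not None:
        e -= float(np.asarray(I, dtype=float) @ u)
    return e


def relaxation_energy_profile(
    w: np.ndarray,
    I: np.ndarray,
    u0: np.ndarray,
    params: DynamicsParams | None = None,
    sample_every: int = 1,
) -> np.ndarray:
    """Energy along a relaxation trajectory, sampled every ``sample_every`` steps.

    The flow is not a gradient descent of the quadratic form: during the
    first ~tau of integration, while the state leaves the near-uniform
    regime created by the 0.5 baseline of the gain, E can transiently rise.
    After that onset transient it decreases monotonically into a minimum
    for the trained weight matrices this package produces.
    """
    if params is None:
        params = DynamicsParams()
    w = np.asarray(w, dtype=float)
    u = np.array(u0, dtype=float)
    I = np.asarray(I, dtype=float)
    step = params.dt / params.tau
    n_steps = int(np.ceil(params.t_max_relax / params.dt))
    out = [energy(w, u, I)]
    for k in range(n_steps):
        g = 0.5 * (1.0 + np.tanh(w @ u + I))
        du = g - u
        u += step * du
        if (k + 1) % sample_every == 0:
            out.append(energy(w, u, I))
        if np.abs(du).max() < params.tol * params.tau:
            break
    return np.asarray(out)


@dataclass(frozen=True)
class Projection:
    """Projection onto the between-pattern discriminant subspace.

    ``basis`` has orthonormal rows (at most P-1 for P patterns); states are
    centered on the global pattern mean before projection.
    """

    basis: np.ndarray
    class_means: np.ndarray
    global_mean: np.ndarray
    eigenvalues: np.ndarray

    def project(self, states: np.ndarray) -> np.ndarray:
        """Project states (shape ``(N,)`` or ``(M, N)``) to subspace coordinates."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        return (states - self.global_mean) @ self.basis.T


def mda_projection(patterns: PatternSet | np.ndarray, rank_tol: float = 1e-10) -> Projection:
    """Multiple discriminant analysis of the stored patterns.

    Builds the between-pattern scatter ``S_b = sum_c (mu_c - mu)(mu_c - mu)^T``
    where ``mu_c`` are the pattern vectors and ``mu`` their mean, and takes
    the top ``P - 1`` eigenvectors as the projection basis (for the default
    3 patterns: a plane).  Eigenvector signs follow a deterministic
    convention (first nonzero component positive).  If patterns coincide,
    the scatter is rank-deficient and fewer basis vectors are returned,
    with a warning.
    """
    import warnings

    if isinstance(patterns, PatternSet):
        mus = np.stack([patterns.vector(pid) for pid in patterns.ids]).astype(float)
    else:
        mus = np.atleast_2d(np.asarray(patterns, dtype=float))
    P = mus.shape[0]
    if P < 2:
        raise ValueError("need at least 2 patterns for a discriminant projection")
    mu = mus.mean(axis=0)
    centered = mus - mu
    s_b = centered.T @ centered
    evals, evecs = np.linalg.eigh(s_b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = min(P - 1, int(np.sum(evals > rank_tol * max(evals.max(), 1.0))))
    if keep < P - 1:
        warnings.warn(
            f"between-pattern scatter has rank {keep} < P-1 = {P - 1}; "
            "patterns are not all distinct",
            RuntimeWarning,
            stacklevel=2,
        )
    basis = evecs[:, :keep].T.copy()
    for row in basis:
        nz = row[np.abs(row) > 1e-12]
        if nz.size and nz[0] < 0:
            row *= -1.0
    return Projection(
        basis=basis, class_means=mus, global_mean=mu, eigenvalues=evals[:keep]
    )


@dataclass(frozen=True)
class LandscapeGrid:
    """Smoothed energy map over the 2-D projection plane.

    ``mean_energy[iy, ix]`` is the mean energy of the ``k`` sampled states
    nearest to the cell center; ``n_in_cell`` counts samples falling inside
    the cell itself, with zero marking cells whose smoothed value is pure
    extrapolation (flagged by ``empty``).
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    mean_energy: np.ndarray
    n_in_cell: np.ndarray

    @property
    def empty(self) -> np.ndarray:
        return self.n_in_cell == 0

    def to_dataframe(self) -> pd.DataFrame:
        xs, ys = np.meshgrid(self.x_centers, self.y_centers)
        return pd.DataFrame(
            {
                "x": xs.ravel(),
                "y": ys.ravel(),
                "mean_energy": self.mean_energy.ravel(),
                "n_samples": self.n_in_cell.ravel(),
            }
        )


def _sample_states(
    w: np.ndarray,
    patterns: PatternSet,
    n_samples: int,
    rng: np.random.Generator,
    params: DynamicsParams,
) -> np.ndarray:
    """Half random sparse binary states, half relaxed states from random
    initializations (covering basin ridges and basin floors)."""
    n = patterns.n_neurons
    n_random = n_samples // 2
    states = np.zeros((n_samples, n))
    for i in range(n_random):
        idx = rng.choice(n, size=patterns.active_size, replace=False)
        states[i, idx] = 1.0
    no_cue = np.zeros(n)
    for i in range(n_random, n_samples):
        u0 = rng.uniform(0.0, 0.1, size=n)
        states[i], _ = relax(w, no_cue, u0, params)
    return states


def energy_landscape(
    w: np.ndarray,
    proj: Projection,
    patterns: PatternSet,
    *,
    n_samples: int = 2000,
    k_neighbors: int = 20,
    grid_res: int = 50,
    rng: np.random.Generator | None = None,
    params: DynamicsParams | None = None,
    include_stored_patterns: bool = True,
) -> LandscapeGrid:
    """Sampled energy landscape of the network in the projection plane.

    States are sampled in the full N-dimensional space, their energies
    computed there, and each grid cell assigned the mean energy of its
    ``k_neighbors`` nearest projected samples.
    """
    if rng is None:
        rng = np.random.default_rng()
    if params is None:
        params = DynamicsParams()
    if proj.basis.shape[0] != 2:
        raise ValueError("energy_landscape needs a 2-D projection")
    states = _sample_states(w, patterns, n_samples, rng, params)
    if include_stored_patterns:
        states = np.vstack([states, proj.class_means])
    energies = np.array([energy(w, u) for u in states])
    coords = proj.project(states)

    pad = 0.05
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo, hi = lo - pad * span, hi + pad * span
    xs = np.linspace(lo[0], hi[0], grid_res)
    ys = np.linspace(lo[1], hi[1], grid_res)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    tree = cKDTree(coords)
    k = min(k_neighbors, len(states))
    _, idx = tree.query(centers, k=k)
    mean_e = energies[idx].mean(axis=1).reshape(grid_res, grid_res)

    ix = np.clip(np.searchsorted(xs, coords[:, 0]) - 1, 0, grid_res - 1)
    iy = np.clip(np.searchsorted(ys, coords[:, 1]) - 1, 0, grid_res - 1)
    counts = np.zeros((grid_res, grid_res), dtype=int)
    np.add.at(counts, (iy, ix), 1)

    return LandscapeGrid(x_centers=xs, y_centers=ys, mean_energy=mean_e, n_in_cell=counts)


@dataclass(frozen=True)
class CapacityCurve:
    """Retrieval success fractions over network sizes and pattern counts."""

    table: pd.DataFrame  # columns: n_neurons, n_patterns, success_fraction, n_trials
    active_size: int
    cue_size: int
    r_threshold: float

    def success(self, n_neurons: int, n_patterns: int) -> float:
        sub = self.table[
            (self.table.n_neurons == n_neurons) & (self.table.n_patterns == n_patterns)
        ]
        return float(sub.success_fraction.iloc[0])


def _random_patterns(
    n_neurons: int, n_patterns: int, active_size: int, rng: np.random.Generator
) -> np.ndarray:
    pats = np.zeros((n_patterns, n_neurons))
    for p in pats:
        p[rng.choice(n_neurons, size=active_size, replace=False)] = 1.0
    return pats


def capacity_curve(
    n_list,
    p_list,
    *,
    active_size: int = 14,
    cue_size: int = 4,
    n_trials: int = 200,
    r_threshold: float = 0.7,
    rng: np.random.Generator | None = None,
    S: float = 0.8,
    s0: float = 1.0,
    cue_strength: float = 5.0,
    trials_per_network: int = 20,
    params: DynamicsParams | None = None,
) -> CapacityCurve:
    """Storage capacity by direct retrieval testing.

    For each (network size, pattern count): store that many random sparse
    patterns by sequential Hebbian learning, then run retrieval trials —
    a weak cue on ``cue_size`` randomly chosen active neurons of a randomly
    chosen stored pattern, random initial conditions — and count the
    fraction of trials whose relaxed state correlates with the target
    pattern above ``r_threshold``.  Patterns are redrawn every
    ``trials_per_network`` trials so the estimate averages over pattern
    realizations as well as cues and initial conditions.
    """
    if rng is None:
        rng = np.random.default_rng()
    if params is None:
        params = DynamicsParams()
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if active_size > min(n_list):
        raise ValueError("active_size exceeds the smallest network size")
    rows = []
    for n in n_list:
        for p_count in p_list:
            successes = 0
            trials_done = 0
            while trials_done < n_trials:
                pats = _random_patterns(n, p_count, active_size, rng)
                w = np.zeros((n, n))
                zero = np.zeros((n, n))
                for pat in pats:
                    I = training_cue(pat)
                    u0 = rng.uniform(0.0, 0.1, size=n)
                    u, _ = relax(w, I, u0, params)
                    w = update_weights(w, hlp_matrix(u, S), zero, s0)
                batch = min(trials_per_network, n_trials - trials_done)
                for _ in range(batch):
                    target = rng.integers(p_count)
                    active = np.flatnonzero(pats[target])
                    cue_idx = rng.choice(active, size=cue_size, replace=False)
                    I = np.zeros(n)
                    I[cue_idx] = cue_strength
                    u0 = rng.uniform(0.0, 0.1, size=n)
                    u, _ = relax(w, I, u0, params)
                    if np.std(u) > 0:
                        r = float(np.corrcoef(u, pats[target])[0, 1])
                        successes += r > r_threshold
                trials_done += batch
            rows.append(
                {
                    "n_neurons": n,
                    "n_patterns": p_count,
                    "success_fraction": successes / n_trials,
                    "n_trials": n_trials,
                }
            )
    return CapacityCurve(
        table=pd.DataFrame(rows),
        active_size=active_size,
        cue_size=cue_size,
        r_threshold=r_threshold,
    )
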