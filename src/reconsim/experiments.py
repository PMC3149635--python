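"""Experiment drivers: preset protocols, duration sweeps and parameter grids.

The standard nonreinforced-reexposure experiment is: train the unrelated
memory, train the shock memory, reexpose to the context for duration ``t``
(optionally under a drug), then test retrieval with the weak context cue.
A time-related decay event (``w <- (1 - gamma) w``) is inserted between
consecutive learning sessions, modelling the inter-session interval; in
multi-session extinction the repeated reexposures are massed, so decay is
applied only before the first of them.  The decay makes the most recently
reinforced memory the strongest, which is what lets the weak context cue
retrieve the shock attractor preferentially after training.

Drug conditions are session-level overrides: anisomycin (protein-synthesis
inhibition) sets ``S = 0`` for the session's update, memory enhancers raise
``S``, degradation blockade sets ``D = 0``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .patterns import (
    SHOCK,
    UNRELATED,
    PatternSet,
    build_default_patterns,
    build_overlap_patterns,
)
from .plasticity import PlasticityParams
from .protocols import (
    ProtocolSpec,
    SessionSpec,
    run_protocol,
    run_session,
)

__all__ = [
    "standard_sessions",
    "make_protocol",
    "reexposure_sweep",
    "grid_sweep",
    "extinction_onset",
    "overlap_extinction_boundary",
    "retrieval_preference",
    "weights_after",
    "run_preset",
]


def _cell_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-cell protocol seeds derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def standard_sessions(
    t: float | None = None,
    *,
    S_training: float | None = None,
    S_reexposure: float | None = None,
    D_reexposure: float | None = None,
    n_reexposures: int = 1,
    pretest: bool = True,
    test_each_reexposure: bool = False,
) -> list[SessionSpec]:
    """Session list for the standard learn-learn-reexpose-test experiment.

    ``S_training`` overrides S during the shock-memory training session
    (strength-of-training manipulations); ``S_reexposure``/``D_reexposure``
    are the drug condition during reexposure.  With ``n_reexposures > 1``
    the reexposures are massed (single decay event before the first).
    ``t = None`` drops the reexposure block (training-only protocol).
    """
    sess = [
        SessionSpec("TRAIN", pattern_id=UNRELATED, label="train unrelated"),
        SessionSpec("DECAY"),
        SessionSpec("TRAIN", pattern_id=SHOCK, S_override=S_training, label="train shock"),
    ]
    if pretest:
        sess.append(SessionSpec("TEST", label="after training"))
    if t is not None:
        sess.append(SessionSpec("DECAY"))
        for k in range(n_reexposures):
            sess.append(
                SessionSpec(
                    "REEXPOSE",
                    t=t,
                    S_override=S_reexposure,
                    D_override=D_reexposure,
                    label=f"reexposure {k + 1}" if n_reexposures > 1 else "reexposure",
                )
            )
            if test_each_reexposure:
                sess.append(SessionSpec("TEST", label=f"after reexposure {k + 1}"))
        if not test_each_reexposure:
            sess.append(SessionSpec("TEST", label="after reexposure"))
    return sess


def make_protocol(sessions, *, n_replicates=100, seed=0, label="", **fields) -> ProtocolSpec:
    """Convenience constructor for a :class:`ProtocolSpec`."""
    return ProtocolSpec(
        sessions=tuple(sessions), n_replicates=n_replicates, seed=seed, label=label, **fields
    )


def _final_test_row(df: pd.DataFrame) -> pd.Series:
    if df.empty:
        raise ValueError("protocol produced no TEST sessions")
    return df.iloc[-1]


def reexposure_sweep(
    t_values,
    arms: dict[str, dict] | None = None,
    *,
    patterns: PatternSet | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    spec_fields: dict | None = None,
) -> pd.DataFrame:
    """Mean freezing after one reexposure of each duration, per drug arm.

    ``arms`` maps arm name to overrides understood by
    :func:`standard_sessions` (``S_reexposure``, ``D_reexposure``,
    ``S_training``).  Every (t, arm) cell is a fresh protocol run with its
    own replicate set; seeds derive deterministically from ``seed``.
    """
    if arms is None:
        arms = {"vehicle": {}}
    if patterns is None:
        patterns = build_default_patterns()
    t_values = list(t_values)
    cells = [(t, name) for t in t_values for name in arms]
    seeds = _cell_seeds(seed, len(cells))
    rows = []
    for (t, name), cell_seed in zip(cells, seeds):
        sess = standard_sessions(float(t), pretest=False, **arms[name])
        spec = make_protocol(
            sess, n_replicates=n_replicates, seed=cell_seed,
            label=name, **(spec_fields or {}),
        )
        r = _final_test_row(run_protocol(spec, patterns))
        rows.append(
            {
                "t": float(t),
                "arm": name,
                "mean_freezing": r.mean_freezing,
                "sem_freezing": r.sem_freezing,
                "n_replicates": r.n_replicates,
                "n_shock": r.n_shock,
                "n_nonshock": r.n_nonshock,
                "n_unrelated": r.n_unrelated,
                "n_none": r.n_none,
            }
        )
    return pd.DataFrame(rows)


def extinction_onset(curve: pd.DataFrame, threshold: float = 50.0, arm: str | None = None):
    """Smallest reexposure duration at which mean freezing drops below
    ``threshold`` (the midpoint of the 10/90 freezing map); ``None`` if it
    never does."""
    df = curve if arm is None else curve[curve.arm == arm]
    below = df[df.mean_freezing < threshold].sort_values("t")
    return None if below.empty else float(below.t.iloc[0])


_GRID_PARAMS = ("S_training", "S_reexposure", "S_global", "D_reexposure", "D_global", "overlap")


def grid_sweep(
    t_values,
    param: str,
    values,
    *,
    arm: dict | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    patterns: PatternSet | None = None,
    spec_fields: dict | None = None,
) -> pd.DataFrame:
    """Cartesian sweep of reexposure duration against one model parameter.

    ``param`` is one of ``S_training`` (S during shock learning),
    ``S_reexposure`` (S during reexposure), ``S_global`` (both),
    ``D_reexposure`` / ``D_global`` (degradation factor during reexposure),
    or ``overlap`` (shared active neurons between the shock and non-shock
    patterns; values are shared-neuron counts).  ``arm`` supplies fixed
    session overrides applied in every cell (e.g. anisomycin during
    reexposure).  Returns a long-format table, one row per (t, value) cell.
    """
    if param not in _GRID_PARAMS:
        raise ValueError(f"param must be one of {_GRID_PARAMS}, got {param!r}")
    arm = dict(arm or {})
    t_values, values = list(t_values), list(values)
    cells = [(t, v) for v in values for t in t_values]
    seeds = _cell_seeds(seed, len(cells))
    rows = []
    for (t, v), cell_seed in zip(cells, seeds):
        cell_arm = dict(arm)
        cell_patterns = patterns
        fields = dict(spec_fields or {})
        if param == "overlap":
            cell_patterns = build_overlap_patterns(int(v))
        elif param == "S_global":
            cell_arm.setdefault("S_training", v)
            cell_arm.setdefault("S_reexposure", v)
        elif param in ("D_global", "D_reexposure"):
            cell_arm.setdefault("D_reexposure", v)
        else:
            cell_arm.setdefault(param, v)
        if cell_patterns is None:
            cell_patterns = build_default_patterns()
        sess = standard_sessions(float(t), pretest=False, **cell_arm)
        spec = make_protocol(sess, n_replicates=n_replicates, seed=cell_seed, **fields)
        r = _final_test_row(run_protocol(spec, cell_patterns))
        rows.append(
            {
                "t": float(t),
                "param": param,
                "value": float(v),
                "mean_freezing": r.mean_freezing,
                "sem_freezing": r.sem_freezing,
                "n_replicates": r.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def overlap_extinction_boundary(
    k_values=range(0, 15),
    t_values=range(0, 11),
    *,
    active_size: int = 14,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[float | None, pd.DataFrame]:
    """Largest pattern overlap at which extinction still occurs in controls.

    For each shared-neuron count ``k`` the full duration sweep is run under
    vehicle; extinction occurs at that overlap if some duration brings mean
    freezing below the 50% midpoint.  Returns the largest such overlap as a
    percentage of active neurons (``None`` if extinction never occurs) plus
    the full grid.
    """
    grid = grid_sweep(
        t_values, "overlap", list(k_values), n_replicates=n_replicates, seed=seed
    )
    boundary = None
    for k in sorted(set(grid.value)):
        sub = grid[grid.value == k]
        if (sub.mean_freezing < 50.0).any():
            boundary = 100.0 * k / active_size
    return boundary, grid


def retrieval_preference(
    cues: dict[str, tuple[int | None, int]],
    *,
    n_sets: int = 10,
    n_replicates: int = 100,
    seed: int = 0,
    patterns: PatternSet | None = None,
    strength: float = 0.1,
    inter_training_decay: bool = False,
) -> pd.DataFrame:
    """Attractor-retrieval statistics after learning memories 1 and 2.

    ``cues`` maps condition name to ``(pattern_id, n_cue)``: a weak cue on
    the first ``n_cue`` active neurons of that pattern, or no cue at all for
    ``pattern_id = None``.  Each condition is evaluated over ``n_sets``
    independent sets of ``n_replicates`` retrievals on freshly trained
    weights, mirroring how retrieval probabilities are usually reported
    (mean ± SEM over sets).  By default the two memories are trained
    back-to-back (no inter-session decay), so both attractors have equal
    strength and free recall lands on either with similar probability.
    """
    from .dynamics import classify_attractor, relax
    from .protocols import random_initial_state

    if patterns is None:
        patterns = build_default_patterns()
    train_sessions = standard_sessions(None, pretest=False)
    if not inter_training_decay:
        train_sessions = [s for s in train_sessions if s.kind != "DECAY"]
    rows = []
    set_seeds = _cell_seeds(seed, n_sets)
    for set_idx, set_seed in enumerate(set_seeds):
        rng = np.random.default_rng(set_seed)
        w = weights_after(train_sessions, seed=set_seed, patterns=patterns)
        for name, (pid, n_cue) in cues.items():
            I = np.zeros(patterns.n_neurons)
            if pid is not None:
                active = np.flatnonzero(patterns.vector(pid))[:n_cue]
                I[active] = strength
            counts = {1: 0, 2: 0, 3: 0, None: 0}
            for _ in range(n_replicates):
                u, _ = relax(w, I, random_initial_state(patterns.n_neurons, rng))
                counts[classify_attractor(u, patterns)] += 1
            for pid_out, c in counts.items():
                rows.append(
                    {
                        "cue": name,
                        "set": set_idx,
                        "retrieved": "none" if pid_out is None else f"pattern{pid_out}",
                        "fraction": c / n_replicates,
                    }
                )
    return pd.DataFrame(rows)


def weights_after(
    sessions,
    *,
    seed: int = 0,
    patterns: PatternSet | None = None,
    spec_fields: dict | None = None,
) -> np.ndarray:
    """Weight matrix of a single replicate after running ``sessions``.

    Useful for energy-landscape snapshots of a protocol stage.
    """
    if patterns is None:
        patterns = build_default_patterns()
    spec = make_protocol(sessions, n_replicates=1, seed=seed, **(spec_fields or {}))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w = np.zeros((patterns.n_neurons, patterns.n_neurons))
    for s in spec.sessions:
        w = run_session(w, s, spec, patterns, rng)
    return w


# ---------------------------------------------------------------------------
# preset execution


def run_preset(
    name: str,
    *,
    seed: int | None = None,
    n_replicates: int | None = None,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """Run a named preset experiment and return its tidy result table.

    Presets are YAML files shipped with the package (see
    :func:`reconsim.presets.available_presets`).  ``overrides`` may adjust
    scalar settings (``seed``, ``n_replicates``, ``S``, ``D``, ``gamma``,
    ``test_strength``, ``r_threshold``, ``sigmoid_midpoint``,
    ``sigmoid_slope``) or force session-level drug values
    (``S_reexposure``, ``D_reexposure``, ``S_training``, ``t``) across all
    arms.
    """
    from .presets import load_preset

    cfg = load_preset(name)
    overrides = dict(overrides or {})
    if seed is None:
        seed = int(overrides.pop("seed", cfg.get("seed", 0)))
    if n_replicates is None:
        n_replicates = int(overrides.pop("n_replicates", cfg.get("n_replicates", 100)))

    plast_kw = {k: float(overrides.pop(k)) for k in ("S", "D", "gamma", "s0") if k in overrides}
    spec_fields = {}
    for k in ("test_strength", "r_threshold", "sigmoid_midpoint", "sigmoid_slope"):
        if k in overrides:
            spec_fields[k] = float(overrides.pop(k))
    if plast_kw:
        spec_fields["plasticity"] = replace(PlasticityParams(), **plast_kw)
    session_over = {
        k: overrides.pop(k)
        for k in ("S_reexposure", "D_reexposure", "S_training", "t")
        if k in overrides
    }
    if overrides:
        raise ValueError(f"unknown overrides: {sorted(overrides)}")

    kind = cfg.get("kind", "protocol")
    if kind == "protocol":
        return _run_protocol_preset(cfg, seed, n_replicates, spec_fields, session_over)
    if kind == "sweep":
        arms = {
            name: _apply_session_overrides_to_arm(dict(arm or {}), session_over)
            for name, arm in cfg["arms"].items()
        }
        t_values = cfg["t_values"]
        if "t" in session_over:
            t_values = [float(session_over["t"])]
        df = reexposure_sweep(
            t_values, arms, n_replicates=n_replicates, seed=seed, spec_fields=spec_fields
        )
        df.insert(0, "preset", cfg["label"])
        return df
    if kind == "grid":
        frames = []
        panels = cfg["panels"]
        panel_seeds = _cell_seeds(seed, len(panels))
        for panel, pseed in zip(panels, panel_seeds):
            arm = _apply_session_overrides_to_arm(dict(panel.get("arm", {})), session_over)
            df = grid_sweep(
                panel.get("t_values", cfg.get("t_values")),
                panel["param"],
                panel["values"],
                arm=arm,
                n_replicates=n_replicates,
                seed=pseed,
                spec_fields=spec_fields,
            )
            df.insert(0, "panel", panel.get("name", panel["param"]))
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "preset", cfg["label"])
        return out
    if kind == "retrieval":
        cues = {
            name: (c.get("pattern_id"), c.get("n_cue", 4)) for name, c in cfg["cues"].items()
        }
        df = retrieval_preference(
            cues,
            n_sets=cfg.get("n_sets", 10),
            n_replicates=n_replicates,
            seed=seed,
            strength=cfg.get("strength", 0.1),
        )
        df.insert(0, "preset", cfg["label"])
        return df
    raise ValueError(f"unknown preset kind {kind!r} in preset {name!r}")


def _apply_session_overrides_to_arm(arm: dict, session_over: dict) -> dict:
    for k, v in session_over.items():
        if k == "t":
            continue
        arm[k] = float(v)
    return arm


def _session_from_dict(d: dict, session_over: dict) -> SessionSpec:
    d = dict(d)
    kind = d.pop("kind")
    if kind == "REEXPOSE":
        if "S_reexposure" in session_over:
            d["S_override"] = float(session_over["S_reexposure"])
        if "D_reexposure" in session_over:
            d["D_override"] = float(session_over["D_reexposure"])
        if "t" in session_over:
            d["t"] = float(session_over["t"])
    if kind == "TRAIN" and d.get("pattern_id") == SHOCK and "S_training" in session_over:
        d["S_override"] = float(session_over["S_training"])
    return SessionSpec(kind=kind, **d)


def _run_protocol_preset(cfg, seed, n_replicates, spec_fields, session_over) -> pd.DataFrame:
    frames = []
    for arm_name, arm_cfg in cfg["arms"].items():
        sessions = [_session_from_dict(s, session_over) for s in arm_cfg["sessions"]]
        spec = make_protocol(
            sessions,
            n_replicates=n_replicates,
            seed=seed,
            label=f"{cfg['label']}:{arm_name}",
            **spec_fields,
        )
        df = run_protocol(spec)
        df.insert(0, "arm", arm_name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "preset", cfg["label"])
    return out
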