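"""Behavioral protocols: training, nonreinforced reexposure, retrieval tests.

A protocol is an ordered list of sessions run on one evolving weight matrix:

* ``TRAIN`` — present a full pattern at training strength and apply one
  plasticity update from the steady state reached.
* ``REEXPOSE`` — nonreinforced reexposure of duration ``t`` in ``[0, 10]``.
  The cue is a sigmoid-weighted mix of the shock and non-shock training
  cues: short sessions resemble the shock memory (the animal still
  perceives the context as dangerous), long sessions resemble the non-shock
  memory, intermediate ``t`` gives ambiguous cues.  One plasticity update
  is applied from the steady state, with optional drug overrides of ``S``
  (protein-synthesis manipulations) and ``D`` (degradation manipulations).
* ``TEST`` — weak context cue, relax, classify the retrieved attractor.
  Retrieval of the shock pattern scores 90% freezing, anything else 10%.
  Tests never change weights.
* ``DECAY`` — discrete inter-session decay event ``w <- (1 - gamma) w``.

Each replicate reruns the whole session sequence from scratch with its own
random initial activations (uniform on ``[0, 0.1]``); reported freezing is
the mean ± SEM over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import I_MAX, DynamicsParams, classify_attractor, relax
from .patterns import (
    NONSHOCK,
    SHOCK,
    UNRELATED,
    PatternSet,
    test_cue,
    training_cue,
)
from .plasticity import (
    PlasticityParams,
    apply_decay,
    hlp_matrix,
    mid_matrix,
    mismatch_vector,
    normalize_cue,
    update_weights,
)

__all__ = [
    "T_MIN",
    "T_MAX",
    "FREEZING_SHOCK",
    "FREEZING_BASELINE",
    "SessionSpec",
    "ProtocolSpec",
    "FreezingStats",
    "sigmoid_f",
    "mixed_cue",
    "random_initial_state",
    "run_session",
    "run_test",
    "run_protocol",
]

T_MIN = 0.0
T_MAX = 10.0

#: Freezing (% of test duration) when the shock attractor is retrieved / otherwise.
FREEZING_SHOCK = 90.0
FREEZING_BASELINE = 10.0

#: Initial activations are drawn uniformly from [0, U0_MAX].
U0_MAX = 0.1


@dataclass(frozen=True)
class SessionSpec:
    """One session of a protocol.

    kind : one of {"TRAIN", "TRAIN_UNRELATED", "REEXPOSE", "TEST", "DECAY"}.
    pattern_id : pattern presented in TRAIN sessions (TRAIN_UNRELATED
        defaults to the unrelated pattern 1).
    t : reexposure duration in [0, 10] (REEXPOSE only).
    S_override, D_override : drug conditions for this session's plasticity
        update; ``None`` means the protocol's baseline value.
    label : free text carried into the result table.
    """

    kind: str
    pattern_id: int | None = None
    t: float | None = None
    S_override: float | None = None
    D_override: float | None = None
    label: str = ""

    _KINDS = ("TRAIN", "TRAIN_UNRELATED", "REEXPOSE", "TEST", "DECAY")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown session kind {self.kind!r}; expected one of {self._KINDS}")
        if self.kind == "TRAIN" and self.pattern_id is None:
            raise ValueError("TRAIN sessions need a pattern_id")
        if self.kind == "REEXPOSE":
            if self.t is None or not T_MIN <= self.t <= T_MAX:
                raise ValueError(f"REEXPOSE needs t in [{T_MIN}, {T_MAX}], got {self.t}")
        for name in ("S_override", "D_override"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class ProtocolSpec:
    """A full protocol: session sequence, replicate count, parameters, seed."""

    sessions: tuple[SessionSpec, ...]
    n_replicates: int = 100
    seed: int = 0
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    I_max: float = I_MAX
    test_strength: float = 0.1
    r_threshold: float = 0.7
    sigmoid_midpoint: float = (T_MIN + T_MAX) / 2.0
    sigmoid_slope: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        object.__setattr__(self, "sessions", tuple(self.sessions))


@dataclass(frozen=True)
class FreezingStats:
    """Freezing summary for one test session over replicates."""

    mean: float
    sem: float
    counts: dict[int | None, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def sigmoid_f(
    t: float | np.ndarray,
    midpoint: float = (T_MIN + T_MAX) / 2.0,
    slope: float = 1.0,
) -> float | np.ndarray:
    """Logistic mixing weight ``f(t) = 1 / (1 + exp(-slope (t - midpoint)))``.

    Monotone from ~0 at ``t = 0`` to ~1 at ``t = 10``; any monotone map onto
    [0, 1] gives qualitatively similar protocol outcomes, shifting only the
    durations at which regime transitions occur.
    """
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(t, dtype=float) - midpoint)))


def mixed_cue(
    t: float,
    patterns: PatternSet,
    I_max: float = I_MAX,
    midpoint: float = (T_MIN + T_MAX) / 2.0,
    slope: float = 1.0,
) -> np.ndarray:
    """Reexposure cue ``I(t) = (1 - f(t)) cue_shock + f(t) cue_nonshock``.

    Interpolates between the two training cues as the session lengthens;
    context neurons receive ``+I_max`` at every ``t`` since both patterns
    activate them.
    """
    if not T_MIN <= t <= T_MAX:
        raise ValueError(f"t must be in [{T_MIN}, {T_MAX}], got {t}")
    f = float(sigmoid_f(t, midpoint, slope))
    cue2 = training_cue(patterns.vector(SHOCK), I_max)
    cue3 = training_cue(patterns.vector(NONSHOCK), I_max)
    return (1.0 - f) * cue2 + f * cue3


def random_initial_state(n_neurons: int, rng: np.random.Generator) -> np.ndarray:
    """Random initial activations, uniform on [0, 0.1] per neuron."""
    return rng.uniform(0.0, U0_MAX, size=n_neurons)


def _session_cue(s: SessionSpec, spec: ProtocolSpec, patterns: PatternSet) -> np.ndarray:
    if s.kind == "TRAIN":
        return training_cue(patterns.vector(s.pattern_id), spec.I_max)
    if s.kind == "TRAIN_UNRELATED":
        pid = s.pattern_id if s.pattern_id is not None else UNRELATED
        return training_cue(patterns.vector(pid), spec.I_max)
    if s.kind == "REEXPOSE":
        return mixed_cue(s.t, patterns, spec.I_max, spec.sigmoid_midpoint, spec.sigmoid_slope)
    raise ValueError(f"session kind {s.kind!r} has no cue")


def run_session(
    w: np.ndarray,
    s: SessionSpec,
    spec: ProtocolSpec,
    patterns: PatternSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run one weight-changing session and return the updated weight matrix.

    TRAIN / TRAIN_UNRELATED / REEXPOSE sessions relax the network from a
    random initial state under the session cue and apply one plasticity
    update computed from the steady state; DECAY applies the inter-session
    decay; TEST returns the weights unchanged (tests are pure readouts —
    use :func:`run_test` for the freezing measurement).
    """
    if s.kind == "DECAY":
        return apply_decay(w, spec.plasticity.gamma)
    if s.kind == "TEST":
        return w

    I = _session_cue(s, spec, patterns)
    u0 = random_initial_state(patterns.n_neurons, rng)
    u, converged = relax(w, I, u0, spec.dynamics)
    if not converged:
        warnings.warn(
            f"relaxation did not reach tolerance in session {s.kind} {s.label!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    S_eff = spec.plasticity.S if s.S_override is None else s.S_override
    D_eff = spec.plasticity.D if s.D_override is None else s.D_override
    i_hat = normalize_cue(I, spec.I_max)
    m = mismatch_vector(i_hat, u)
    hlp = hlp_matrix(u, S_eff)
    mid = mid_matrix(u, m, D_eff)
    return update_weights(w, hlp, mid, spec.plasticity.s0)


def _test_once(
    w: np.ndarray,
    spec: ProtocolSpec,
    patterns: PatternSet,
    rng: np.random.Generator,
) -> int | None:
    I = test_cue(patterns, spec.test_strength)
    u0 = random_initial_state(patterns.n_neurons, rng)
    u, _ = relax(w, I, u0, spec.dynamics)
    return classify_attractor(u, patterns, spec.r_threshold)


def _freezing_of(label: int | None) -> float:
    return FREEZING_SHOCK if label == SHOCK else FREEZING_BASELINE


def _aggregate(labels: list[int | None]) -> FreezingStats:
    scores = np.array([_freezing_of(lab) for lab in labels], dtype=float)
    counts: dict[int | None, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    sem = float(scores.std(ddof=1) / np.sqrt(len(scores))) if len(scores) > 1 else 0.0
    return FreezingStats(mean=float(scores.mean()), sem=sem, counts=counts)


def run_test(
    w: np.ndarray,
    patterns: PatternSet,
    n_reps: int,
    rng: np.random.Generator,
    spec: ProtocolSpec | None = None,
) -> FreezingStats:
    """Retrieval test on fixed weights: relax ``n_reps`` times under the
    weak context cue from fresh random initial states, classify each
    retrieved attractor and map to freezing (90% for the shock pattern,
    10% otherwise)."""
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if spec is None:
        spec = ProtocolSpec(sessions=())
    labels = [_test_once(w, spec, patterns, rng) for _ in range(n_reps)]
    return _aggregate(labels)


def run_protocol(
    spec: ProtocolSpec,
    patterns: PatternSet | None = None,
) -> pd.DataFrame:
    """Execute a full protocol over replicates and tabulate freezing per test.

    Each replicate runs the entire session sequence on its own copy of the
    weights, with an independent RNG stream spawned from the protocol seed,
    so results do not depend on replicate execution order.  Returns a tidy
    table with one row per TEST session: protocol label, session index,
    session label, mean freezing, SEM and per-attractor retrieval counts.
    """
    from .patterns import build_default_patterns

    if patterns is None:
        patterns = build_default_patterns()
    test_positions = [i for i, s in enumerate(spec.sessions) if s.kind == "TEST"]
    first_train = next(
        (i for i, s in enumerate(spec.sessions) if s.kind.startswith("TRAIN")), None
    )
    if test_positions and (first_train is None or test_positions[0] < first_train):
        warnings.warn(
            "protocol runs a TEST before any TRAIN session; freezing will be at baseline",
            RuntimeWarning,
            stacklevel=2,
        )

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    labels_per_test: dict[int, list[int | None]] = {i: [] for i in test_positions}
    for child in streams:
        rng = np.random.default_rng(child)
        w = np.zeros((patterns.n_neurons, patterns.n_neurons))
        for i, s in enumerate(spec.sessions):
            if s.kind == "TEST":
                labels_per_test[i].append(_test_once(w, spec, patterns, rng))
            else:
                w = run_session(w, s, spec, patterns, rng)

    rows = []
    for i in test_positions:
        stats = _aggregate(labels_per_test[i])
        rows.append(
            {
                "protocol": spec.label,
                "session_index": i,
                "session_label": spec.sessions[i].label,
                "mean_freezing": stats.mean,
                "sem_freezing": stats.sem,
                "n_replicates": stats.n,
                "n_shock": stats.counts.get(SHOCK, 0),
                "n_nonshock": stats.counts.get(NONSHOCK, 0),
                "n_unrelated": stats.counts.get(UNRELATED, 0),
                "n_none": stats.counts.get(None, 0),
            }
        )
    return pd.DataFrame(rows)


def with_overrides(spec: ProtocolSpec, **kwargs) -> ProtocolSpec:
    """Return a copy of ``spec`` with fields replaced (seed, labels, params...)."""
    return replace(spec, **kwargs)
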