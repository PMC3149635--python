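import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reconsim import (
    PlasticityParams,
    apply_decay,
    hlp_matrix,
    mid_matrix,
    mismatch_vector,
    normalize_cue,
    update_weights,
)


def prose_hlp(u_pre: float, u_post: float, S: float) -> float:
    """Brute-force oracle for the Hebbian rule as stated case by case:
    active->active +S, active->silent -S, silent presynaptic 0."""
    if u_pre == 0:
        return 0.0
    return S if u_post == 1 else -S


def prose_mid(u_pre: float, i_hat_post: float, u_post: float, D: float) -> float:
    """Brute-force oracle for mismatch degradation: connections from active
    units change by +D towards cue-active-but-suppressed units and -D
    towards cue-suppressed-but-active units; nothing else changes."""
    if u_pre == 0:
        return 0.0
    if i_hat_post == 1 and u_post == 0:
        return D
    if i_hat_post == 0 and u_post == 1:
        return -D
    return 0.0


class TestNormalizeCue:
    @pytest.mark.parametrize("I,expected", [(5.0, 1.0), (-5.0, 0.0), (0.0, 0.5)])
    def test_affine_endpoints(self, I, expected):
        assert normalize_cue(np.array([I])) == pytest.approx(expected)

    def test_rejects_nonpositive_imax(self):
        with pytest.raises(ValueError):
            normalize_cue(np.zeros(3), I_max=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=20))
    def test_range_and_monotonicity(self, currents):
        I = np.sort(np.array(currents))
        i_hat = normalize_cue(I)
        assert np.all((i_hat >= 0) & (i_hat <= 1))
        assert np.all(np.diff(i_hat) >= 0)


def test_sign_contract_exhaustive_binary_table():
    """Every (u_pre, u_post, i_hat_post) in {0,1}^3 must reproduce the
    discrete weight-change rules; entries are in {-S, 0, +S} and {-D, 0, +D}."""
    S, D = 0.8, 1.25
    for u_pre, u_post, ih_post in itertools.product([0.0, 1.0], repeat=3):
        u = np.array([u_pre, u_post])
        i_hat = np.array([u_pre, ih_post])  # presynaptic cue entry irrelevant
        hlp = hlp_matrix(u, S)
        mid = mid_matrix(u, mismatch_vector(i_hat, u), D)
        assert hlp[1, 0] == pytest.approx(prose_hlp(u_pre, u_post, S))
        assert mid[1, 0] == pytest.approx(prose_mid(u_pre, ih_post, u_post, D))
        assert any(hlp[1, 0] == pytest.approx(v) for v in (-S, 0.0, S))
        assert any(mid[1, 0] == pytest.approx(v) for v in (-D, 0.0, D))


class TestHebbian:
    def test_coactive_pair_strengthens_by_S(self):
        hlp = hlp_matrix(np.array([1.0, 1.0]), 0.8)
        assert hlp[1, 0] == pytest.approx(0.8)

    def test_active_to_silent_weakens_by_S(self):
        hlp = hlp_matrix(np.array([1.0, 0.0]), 0.8)
        assert hlp[1, 0] == pytest.approx(-0.8)

    def test_silent_presynaptic_changes_nothing(self):
        hlp = hlp_matrix(np.array([0.0, 1.0]), 0.8)
        assert hlp[1, 0] == 0.0

    def test_S_zero_blocks_all_hebbian_change(self, rng):
        assert np.all(hlp_matrix(rng.random(50), 0.0) == 0.0)


class TestMismatch:
    def test_cue_active_suppressed_unit_has_plus_one(self):
        m = mismatch_vector(np.array([1.0]), np.array([0.0]))
        assert m[0] == 1.0

    def test_cue_suppressed_active_unit_has_minus_one(self):
        m = mismatch_vector(np.array([0.0]), np.array([1.0]))
        assert m[0] == -1.0

    def test_matching_attractor_gives_zero_mismatch(self, rng):
        u = rng.random(30)
        assert np.all(mismatch_vector(u, u) == 0.0)

    def test_degradation_values(self):
        u = np.array([1.0, 0.0, 1.0])
        i_hat = np.array([1.0, 1.0, 0.0])  # unit 1 is AS, unit 2 is SA
        mid = mid_matrix(u, mismatch_vector(i_hat, u), 1.25)
        assert mid[1, 0] == pytest.approx(1.25)
        assert mid[2, 0] == pytest.approx(-1.25)

    def test_zero_mismatch_or_zero_D_gives_zero_matrix(self, rng):
        u = rng.random(40)
        assert np.all(mid_matrix(u, np.zeros(40), 1.25) == 0.0)
        assert np.all(mid_matrix(u, rng.random(40), 0.0) == 0.0)

    def test_silent_presynaptic_column_is_zero_in_both_terms(self, rng):
        u = rng.random(20)
        u[[3, 7]] = 0.0
        m = mismatch_vector(rng.random(20), u)
        assert np.all(hlp_matrix(u, 0.8)[:, [3, 7]] == 0.0)
        assert np.all(mid_matrix(u, m, 1.25)[:, [3, 7]] == 0.0)


class TestUpdateWeights:
    def test_truncation_at_saturation_bound(self):
        w = np.array([[0.0, 0.9], [-0.9, 0.0]])
        hlp = np.array([[0.0, 0.8], [-0.8, 0.0]])
        out = update_weights(w, hlp, np.zeros((2, 2)), s0=1.0)
        assert out[0, 1] == 1.0
        assert out[1, 0] == -1.0

    def test_zero_changes_are_identity_with_zero_diagonal(self, rng):
        w = rng.uniform(-0.9, 0.9, size=(10, 10))
        out = update_weights(w, np.zeros((10, 10)), np.zeros((10, 10)), s0=1.0)
        off = ~np.eye(10, dtype=bool)
        assert np.allclose(out[off], w[off])
        assert np.all(np.diag(out) == 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_saturation_holds_under_random_update_sequences(self, seed):
        rng = np.random.default_rng(seed)
        n, s0 = 12, 1.0
        w = np.zeros((n, n))
        for _ in range(8):
            u = rng.random(n)
            m = mismatch_vector(rng.random(n), u)
            w = update_weights(w, hlp_matrix(u, 0.8), mid_matrix(u, m, 1.25), s0)
            assert np.abs(w).max() <= s0
            assert np.all(np.diag(w) == 0.0)


class TestDecay:
    def test_fractional_decay(self):
        w = np.full((3, 3), 1.0)
        assert np.allclose(apply_decay(w, 0.15), 0.85)

    def test_zero_gamma_is_identity_and_zero_is_fixed_point(self):
        w = np.random.default_rng(0).normal(size=(4, 4))
        assert np.allclose(apply_decay(w, 0.0), w)
        assert np.all(apply_decay(np.zeros((4, 4)), 0.15) == 0.0)

    @pytest.mark.parametrize("gamma", [-0.1, 1.0, 2.0])
    def test_rejects_gamma_outside_unit_interval(self, gamma):
        with pytest.raises(ValueError):
            apply_decay(np.zeros((2, 2)), gamma)


@pytest.mark.parametrize(
    "bad", [dict(S=-1), dict(D=-0.1), dict(gamma=1.0), dict(gamma=-0.1), dict(s0=0)]
)
def test_plasticity_params_validation(bad):
    with pytest.raises(ValueError):
        PlasticityParams(**bad)
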