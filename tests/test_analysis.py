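import numpy as np
import pytest

from reconsim import (
    DynamicsParams,
    SHOCK,
    build_default_patterns,
    capacity_curve,
    energy,
    energy_landscape,
    mda_projection,
    relaxation_energy_profile,
    test_cue as context_cue,
)


class TestEnergy:
    def test_zero_weights_or_zero_state_give_zero(self, rng):
        assert energy(np.zeros((10, 10)), rng.random(10)) == 0.0
        assert energy(rng.normal(size=(10, 10)), np.zeros(10)) == 0.0

    def test_cue_term_is_linear(self, rng):
        w = rng.normal(size=(10, 10))
        u, I = rng.random(10), rng.normal(size=10)
        assert energy(w, u, I) == pytest.approx(energy(w, u) - I @ u)

    def test_trained_pattern_lies_below_random_states(self, trained_weights, patterns, rng):
        """The stored shock pattern is an energy minimum: deeper than the
        median random sparse binary state."""
        e_pattern = energy(trained_weights, patterns.vector(SHOCK))
        randoms = []
        for _ in range(100):
            u = np.zeros(100)
            u[rng.choice(100, size=14, replace=False)] = 1.0
            randoms.append(energy(trained_weights, u))
        assert e_pattern < np.median(randoms)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            energy(np.zeros((3, 3)), np.zeros(4))


class TestEnergyDescent:
    def test_energy_nonincreasing_after_onset_transient(self, trained_weights, patterns, rng):
        """Past the first time-constant of integration (the rise out of the
        near-uniform regime), energy decreases monotonically into the
        attractor on protocol weight matrices."""
        params = DynamicsParams()
        skip = int(params.tau / params.dt)  # one tau of Euler steps
        for I in (context_cue(patterns), np.zeros(100)):
            for _ in range(3):
                prof = relaxation_energy_profile(
                    trained_weights, I, rng.uniform(0, 0.1, 100), params
                )
                tail = np.diff(prof[skip:])
                assert np.all(tail <= 1e-8)
                assert prof[-1] < prof[0]


class TestProjection:
    def test_three_patterns_give_plane(self, patterns):
        proj = mda_projection(patterns)
        assert proj.basis.shape == (2, 100)

    def test_basis_rows_are_orthonormal(self, patterns):
        proj = mda_projection(patterns)
        assert np.allclose(proj.basis @ proj.basis.T, np.eye(2), atol=1e-10)

    def test_scatter_rank_bound(self, rng):
        mus = rng.random((5, 30))
        proj = mda_projection(mus)
        assert proj.basis.shape[0] <= 4

    def test_distinct_patterns_project_to_distinct_points(self, patterns):
        proj = mda_projection(patterns)
        pts = proj.project(proj.class_means)
        d01 = np.linalg.norm(pts[0] - pts[1])
        d02 = np.linalg.norm(pts[0] - pts[2])
        d12 = np.linalg.norm(pts[1] - pts[2])
        assert min(d01, d02, d12) > 1.0

    def test_projection_preserves_class_mean_distances(self, patterns):
        """The basis spans the centered class means, so projecting them is
        an isometry on their pairwise distances."""
        proj = mda_projection(patterns)
        pts = proj.project(proj.class_means)
        centered = proj.class_means - proj.global_mean
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(pts[i] - pts[j]) == pytest.approx(
                    np.linalg.norm(centered[i] - centered[j]), abs=1e-8
                )

    def test_identical_patterns_warn_and_reduce_rank(self):
        mus = np.ones((3, 10))
        mus[0, :5] = 0.0
        mus[1] = mus[0]  # two coincident classes
        with pytest.warns(RuntimeWarning, match="rank"):
            proj = mda_projection(mus)
        assert proj.basis.shape[0] == 1

    def test_single_pattern_rejected(self):
        with pytest.raises(ValueError):
            mda_projection(np.ones((1, 10)))


class TestLandscape:
    def test_zero_weights_give_flat_landscape(self, patterns, rng):
        proj = mda_projection(patterns)
        grid = energy_landscape(
            np.zeros((100, 100)), proj, patterns,
            n_samples=200, grid_res=12, rng=rng,
        )
        assert np.allclose(grid.mean_energy, 0.0, atol=1e-12)

    def test_minima_at_stored_patterns_only(self, trained_weights, patterns, rng):
        """After learning memories 1 and 2, the landscape dips at their
        projected locations but not at memory 3's."""
        proj = mda_projection(patterns)
        grid = energy_landscape(
            trained_weights, proj, patterns, n_samples=800, grid_res=25, rng=rng
        )

        def cell_energy(point):
            ix = np.argmin(np.abs(grid.x_centers - point[0]))
            iy = np.argmin(np.abs(grid.y_centers - point[1]))
            return grid.mean_energy[iy, ix]

        pts = proj.project(proj.class_means)
        e1, e2, e3 = (cell_energy(p) for p in pts)
        floor = np.percentile(grid.mean_energy, 25)
        assert e1 < floor and e2 < floor
        assert e3 > min(e1, e2)

    def test_empty_cells_are_flagged_not_zero(self, patterns, rng):
        proj = mda_projection(patterns)
        grid = energy_landscape(
            np.zeros((100, 100)), proj, patterns, n_samples=60, grid_res=20, rng=rng
        )
        assert grid.empty.any()
        df = grid.to_dataframe()
        assert {"x", "y", "mean_energy", "n_samples"} <= set(df.columns)


class TestCapacity:
    def test_single_pattern_is_always_retrievable(self, rng):
        curve = capacity_curve([60], [1], n_trials=20, rng=rng)
        assert curve.success(60, 1) == 1.0

    def test_same_seed_gives_identical_curve(self):
        a = capacity_curve([60], [2, 4], n_trials=20, rng=np.random.default_rng(3))
        b = capacity_curve([60], [2, 4], n_trials=20, rng=np.random.default_rng(3))
        assert a.table.equals(b.table)

    def test_success_fractions_are_probabilities(self, rng):
        curve = capacity_curve([60], [2, 6], n_trials=20, rng=rng)
        assert ((curve.table.success_fraction >= 0) & (curve.table.success_fraction <= 1)).all()

    def test_rejects_degenerate_inputs(self, rng):
        with pytest.raises(ValueError):
            capacity_curve([60], [1], n_trials=0, rng=rng)
        with pytest.raises(ValueError):
            capacity_curve([10], [1], active_size=14, rng=rng)
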