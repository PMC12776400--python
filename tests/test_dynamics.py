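import numpy as np
import pytest

from wellmix import (
    CalibrationConstants,
    PipetteConfig,
    WellGeometry,
    apply_recirculation,
    build_grid,
    build_rate_matrix,
    compute_footprint,
    cycle_operator,
    initial_condition,
    jet_axis,
    recirculation_coefficient,
    simulate,
)
from wellmix.jet import JetFootprint
from wellmix.errors import InvalidParameterError

from conftest import euler_evolve


def footprint_of(grid, geometry, angle=0.0, offset=0.0, r_f=0.55):
    axis = jet_axis(PipetteConfig(angle_deg=angle, tip_offset=offset), geometry)
    return compute_footprint(grid, axis, r_f)


class TestRateMatrix:
    def test_empty_footprint_all_baseline(self, grid):
        fp = JetFootprint(cell_indices=frozenset(), fraction=0.0)
        K = build_rate_matrix(grid, fp, jet_strength=8.0)
        off = K.matrix[grid.edges[:, 0], grid.edges[:, 1]]
        assert np.all(off == 1.0)
        assert K.enhanced_edges == frozenset()

    def test_full_footprint_uniform_enhancement(self, grid):
        fp = JetFootprint(
            cell_indices=frozenset(range(grid.n_cells)), fraction=1.0
        )
        K = build_rate_matrix(grid, fp, jet_strength=8.0)
        off = K.matrix[grid.edges[:, 0], grid.edges[:, 1]]
        assert np.all(off == 9.0)
        assert len(K.enhanced_edges) == len(grid.edges)

    def test_enhanced_edges_match_brute_force(self, grid, geometry):
        """Enhanced edges = edges with both centers within the band."""
        fp = footprint_of(grid, geometry, r_f=0.25)
        K = build_rate_matrix(grid, fp, jet_strength=4.0)
        half_width = 0.25 * geometry.radius
        expected = {
            (int(a), int(b))
            for a, b in grid.edges
            if abs(grid.cells[a, 0]) <= half_width
            and abs(grid.cells[b, 0]) <= half_width
        }
        assert K.enhanced_edges == expected
        assert np.all(
            K.matrix[tuple(np.array(sorted(expected)).T)] == 5.0
        )

    def test_symmetric_zero_column_sums(self, grid, geometry):
        K = build_rate_matrix(grid, footprint_of(grid, geometry), 8.0).matrix
        assert np.array_equal(K, K.T)
        assert np.abs(K.sum(axis=0)).max() < 1e-12
        off = K - np.diag(np.diag(K))
        assert off.min() >= 0


class TestCycleOperator:
    def test_zero_time_is_identity(self, grid, geometry):
        K = build_rate_matrix(grid, footprint_of(grid, geometry), 8.0)
        assert np.array_equal(cycle_operator(K, 0.0), np.eye(grid.n_cells))

    def test_two_cell_closed_form(self):
        """exp(tau K) for a single rate-1 pair has the known 2x2 form."""
        from wellmix.dynamics import RateMatrix

        K = RateMatrix(matrix=np.array([[-1.0, 1.0], [1.0, -1.0]]))
        for tau in (0.1, 0.7, 2.3):
            M = cycle_operator(K, tau)
            e = np.exp(-2 * tau)
            expected = 0.5 * np.array([[1 + e, 1 - e], [1 - e, 1 + e]])
            assert M == pytest.approx(expected, abs=1e-12)

    def test_doubly_stochastic_nonnegative(self, grid, geometry):
        K = build_rate_matrix(grid, footprint_of(grid, geometry), 8.0)
        M = cycle_operator(K, 0.3)
        assert np.abs(M.sum(axis=0) - 1).max() < 1e-10
        assert np.abs(M.sum(axis=1) - 1).max() < 1e-10
        assert M.min() >= -1e-12
        assert np.array_equal(M, M.T)

    def test_agrees_with_fine_step_euler(self, grid, geometry):
        """exp(tau K) c0 matches an independent forward-Euler integration.

        The substep count is chosen so the Euler discretization error
        itself sits below the 1e-6 comparison tolerance.
        """
        fp = footprint_of(grid, geometry)
        K = build_rate_matrix(grid, fp, 8.0)
        c0 = initial_condition(grid)
        M = cycle_operator(K, 0.3)
        reference = euler_evolve(K.matrix, c0, 0.3, 200_000)
        assert np.abs(M @ c0 - reference).max() < 1e-6

    def test_negative_time_rejected(self, grid, geometry):
        K = build_rate_matrix(grid, footprint_of(grid, geometry), 8.0)
        with pytest.raises(InvalidParameterError):
            cycle_operator(K, -0.1)


class TestRecirculation:
    @pytest.mark.parametrize(
        "gamma0, S, f, expected",
        [(0.0, 8.0, 0.5, 0.0), (0.02, 8.0, 0.5, 0.08), (1.0, 8.0, 1.0, 0.5)],
    )
    def test_coefficient_formula_and_cap(self, gamma0, S, f, expected):
        assert recirculation_coefficient(gamma0, S, f) == pytest.approx(expected)

    def test_relaxation_preserves_mean_contracts_variance(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(size=50)
        out = apply_recirculation(c, 0.1)
        assert out.mean() == pytest.approx(c.mean(), abs=1e-14)
        assert np.var(out) / np.var(c) == pytest.approx(0.81)

    def test_limits(self):
        c = np.array([0.0, 1.0, 0.4])
        assert np.array_equal(apply_recirculation(c, 0.0), c)
        assert apply_recirculation(c, 1.0) == pytest.approx(
            np.full(3, c.mean())
        )

    @pytest.mark.parametrize("gamma", [-0.1, 1.1])
    def test_out_of_range_gamma_rejected(self, gamma):
        with pytest.raises(InvalidParameterError):
            apply_recirculation(np.ones(3), gamma)


class TestInitialCondition:
    def test_biphasic_top_high(self, grid):
        c = initial_condition(grid)
        assert np.all(c[: 8 * 16] == 0.0)  # rows 0-7 low
        assert np.all(c[8 * 16 :] == 1.0)  # rows 8-15 high
        assert c.mean() == pytest.approx(0.5)

    def test_odd_rows_middle_joins_lower_block(self):
        g = build_grid(WellGeometry(n_x=4, n_z=5))
        c = initial_condition(g)
        # rows 0, 1 and the middle row 2 low; rows 3, 4 high
        assert np.all(c[: 3 * 4] == 0.0)
        assert np.all(c[3 * 4 :] == 1.0)


class TestSimulate:
    def test_zero_cycles(self, geometry, constants):
        traj = simulate(geometry, PipetteConfig(), constants, n_cycles=0)
        assert traj.phi_series.tolist() == [1.0]
        assert traj.concentrations.shape == (1, 256)

    def test_mass_conserved_and_phi_monotone(self, geometry, constants):
        cfg = PipetteConfig(angle_deg=30, tip_offset=0.25,
                            footprint_radius=0.25, jet_strength=4.0)
        traj = simulate(geometry, cfg, constants, 12)
        totals = traj.concentrations.sum(axis=1)
        assert np.abs(totals / totals[0] - 1).max() < 1e-10
        assert np.all(np.diff(traj.phi_series) <= 1e-14)
        assert traj.phi_series[0] == 1.0

    def test_full_schedule_matches_fine_step_integration(
        self, geometry, grid, constants
    ):
        """Three cycles of operator + recirculation equal an independent
        Euler integration of the same piecewise schedule."""
        cfg = PipetteConfig()
        traj = simulate(geometry, cfg, constants, 3)
        fp = footprint_of(grid, geometry, r_f=cfg.footprint_radius)
        K = build_rate_matrix(grid, fp, cfg.jet_strength)
        gamma = recirculation_coefficient(
            constants.gamma0, cfg.jet_strength, fp.fraction, constants.gamma_max
        )
        c = initial_condition(grid)
        for _ in range(3):
            c = euler_evolve(K.matrix, c, constants.tau_c, 150_000)
            c = (1 - gamma) * c + gamma * c.mean()
        assert np.abs(traj.concentrations[-1] - c).max() < 1e-5

    def test_gentle_small_stays_unmixed(self, scenario_trajectories):
        """A weak, narrow jet leaves Phi above 0.05 after 12 cycles."""
        assert scenario_trajectories["gentle_small"].final_phi > 0.05

    def test_near_geometric_decay(self, scenario_trajectories):
        """log Phi falls almost linearly with cycle number after cycle 2."""
        for traj in scenario_trajectories.values():
            slopes = np.diff(np.log(traj.phi_series))[2:]
            assert np.abs(slopes - slopes.mean()).max() < 0.05 * abs(slopes.mean())
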