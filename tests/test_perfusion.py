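"""Three-compartment Darcy solver, MBF and the blinded calibration."""

import itertools

import numpy as np
import pytest

from coroperf import (
    DarcyGrid,
    DarcyParams,
    NumericalError,
    PressureHeadSupply,
    ValidationError,
    calibrate_rest,
    scale_to_stress,
    solve_darcy,
    total_conductance,
)
from coroperf.perfusion import MMHG_TO_PA, scale_conductances


def dense_darcy_oracle(grid, params, g):
    """Independent brute-force assembly: explicit loops over voxels/faces,
    dense numpy solve.  Returns the three pressure fields in mmHg."""
    n = grid.n_cells
    A = np.zeros((3 * n, 3 * n))
    b = np.zeros(3 * n)
    Ks = (params.K1, params.K2, params.K3)
    pv_pa = params.p_veins * MMHG_TO_PA

    def idx(c, i, j, k):
        return c * n + (i * grid.ny + j) * grid.nz + k

    for i, j, k in itertools.product(range(grid.nx), range(grid.ny), range(grid.nz)):
        for c in range(3):
            row = idx(c, i, j, k)
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                ii, jj, kk = i + di, j + dj, k + dk
                if 0 <= ii < grid.nx and 0 <= jj < grid.ny and 0 <= kk < grid.nz:
                    A[row, row] += Ks[c] / grid.h**2
                    A[row, idx(c, ii, jj, kk)] -= Ks[c] / grid.h**2
        r1, r2, r3 = (idx(c, i, j, k) for c in range(3))
        A[r1, r1] += params.beta12
        A[r1, r2] -= params.beta12
        A[r2, r2] += params.beta12 + params.beta23
        A[r2, r1] -= params.beta12
        A[r2, r3] -= params.beta23
        A[r3, r3] += params.beta23 + params.gamma
        A[r3, r2] -= params.beta23
        b[r1] += g[i, j, k]
        b[r3] += params.gamma * pv_pa
    x = np.linalg.solve(A, b)
    return tuple(x[c * n : (c + 1) * n].reshape(grid.shape) / MMHG_TO_PA for c in range(3))


class TestSolveDarcy:
    def test_zero_source_gives_venous_pressure(self, small_grid, params):
        state = solve_darcy(small_grid, params, np.zeros(small_grid.shape))
        for p in (state.p1, state.p2, state.p3):
            assert np.allclose(p, params.p_veins, rtol=0, atol=1e-10)

    def test_uniform_source_closed_form(self, params):
        grid = DarcyGrid(5, 4, 3, 1.5e-3)
        g0 = 0.02
        state = solve_darcy(grid, params, np.full(grid.shape, g0))
        p3 = params.p_veins + g0 / params.gamma / MMHG_TO_PA
        p2 = p3 + g0 / params.beta23 / MMHG_TO_PA
        p1 = p2 + g0 / params.beta12 / MMHG_TO_PA
        assert np.allclose(state.p3, p3, rtol=1e-10)
        assert np.allclose(state.p2, p2, rtol=1e-10)
        assert np.allclose(state.p1, p1, rtol=1e-10)

    @pytest.mark.parametrize("shape", [(3, 3, 3), (4, 4, 4), (4, 3, 2)])
    def test_matches_dense_oracle(self, params, shape):
        grid = DarcyGrid(*shape, 2e-3)
        rng = np.random.default_rng(17)
        g = rng.uniform(0.0, 0.05, size=grid.shape)
        state = solve_darcy(grid, params, g)
        o1, o2, o3 = dense_darcy_oracle(grid, params, g)
        for ours, oracle in ((state.p1, o1), (state.p2, o2), (state.p3, o3)):
            assert np.allclose(ours, oracle, rtol=1e-10)

    def test_global_mass_balance(self, small_grid, params):
        rng = np.random.default_rng(3)
        g = rng.uniform(0.0, 0.05, size=small_grid.shape)
        state = solve_darcy(small_grid, params, g)
        assert state.mass_balance_error < 1e-8

    def test_maximum_principle_and_compartment_ordering(self, small_grid, params):
        rng = np.random.default_rng(5)
        g = rng.uniform(0.0, 0.05, size=small_grid.shape)
        state = solve_darcy(small_grid, params, g)
        assert np.all(state.p3 >= params.p_veins - 1e-10)
        assert np.all(state.p1 >= state.p2 - 1e-10)
        assert np.all(state.p2 >= state.p3 - 1e-10)

    def test_p1_monotone_in_source(self, small_grid, params):
        rng = np.random.default_rng(9)
        g = rng.uniform(0.0, 0.05, size=small_grid.shape)
        base = solve_darcy(small_grid, params, g)
        bumped = solve_darcy(small_grid, params, g + rng.uniform(0.0, 0.01, small_grid.shape))
        assert np.all(bumped.p1 >= base.p1 - 1e-12)

    def test_shape_mismatch_rejected(self, small_grid, params):
        with pytest.raises(ValidationError):
            solve_darcy(small_grid, params, np.zeros((2, 2, 2)))


class TestMbf:
    def test_zero_source_zero_mbf(self, small_grid, params):
        state = solve_darcy(small_grid, params, np.zeros(small_grid.shape))
        assert np.allclose(state.mbf, 0.0, atol=1e-8)

    def test_reference_conversion(self, params):
        # g = 0.02625 1/s at 1.05 g/mL is exactly 150 mL/min/100 g
        grid = DarcyGrid(4, 4, 3, 2e-3, density=1.05)
        state = solve_darcy(grid, params, np.full(grid.shape, 0.02625))
        assert state.mean_mbf == pytest.approx(150.0, rel=1e-9)

    def test_mean_mbf_times_mass_is_total_inflow(self, small_grid, params):
        rng = np.random.default_rng(21)
        g = rng.uniform(0.0, 0.05, size=small_grid.shape)
        state = solve_darcy(small_grid, params, g)
        assert state.mean_mbf * small_grid.total_mass_g / 100.0 == pytest.approx(
            state.total_inflow_ml_min, rel=1e-8
        )


class TestConductance:
    def test_table_defaults(self, params):
        assert total_conductance(params) == pytest.approx(6.5217e-6, rel=1e-4)

    def test_equal_conductances(self):
        p = DarcyParams(beta12=3e-5, beta23=3e-5, gamma=3e-5)
        assert total_conductance(p) == pytest.approx(1e-5, rel=1e-12)

    def test_homogeneous_in_scaling(self, params):
        scaled = scale_conductances(params, 2.5)
        assert total_conductance(scaled) == pytest.approx(2.5 * total_conductance(params))

    def test_stress_scaling_quadruples_total(self, params):
        stressed = scale_to_stress(params)
        assert total_conductance(stressed) / total_conductance(params) == pytest.approx(
            4.0, rel=1e-12
        )

    def test_stress_scaling_composes(self, params):
        twice = scale_to_stress(scale_to_stress(params))
        assert total_conductance(twice) / total_conductance(params) == pytest.approx(16.0)

    def test_stress_scaling_preserves_venous_pressure_and_permeability(self, params):
        stressed = scale_to_stress(params)
        assert stressed.p_veins == 5.0
        assert (stressed.K1, stressed.K2, stressed.K3) == (params.K1, params.K2, params.K3)


class TestCalibration:
    def test_reaches_target_and_resimulates(self, small_grid, params):
        supply = PressureHeadSupply(p_head=60.0)
        cal = calibrate_rest(small_grid, params, supply, target_inflow=1.0)
        assert abs(cal.achieved_inflow - 1.0) <= 0.005
        again = supply.steady(small_grid, cal.params)
        assert again.inflow_per_gram == pytest.approx(cal.achieved_inflow, rel=1e-12)

    def test_target_met_at_unit_factor_returns_base(self, small_grid, params):
        supply = PressureHeadSupply(p_head=60.0)
        target = supply.steady(small_grid, params).inflow_per_gram
        cal = calibrate_rest(small_grid, params, supply, target_inflow=target)
        assert cal.lam == pytest.approx(1.0, rel=1e-12)

    def test_larger_target_needs_larger_factor(self, small_grid, params):
        supply = PressureHeadSupply(p_head=60.0)
        lo = calibrate_rest(small_grid, params, supply, target_inflow=0.8)
        hi = calibrate_rest(small_grid, params, supply, target_inflow=1.6)
        assert hi.lam > lo.lam

    def test_unreachable_target_errors(self, small_grid, params):
        supply = PressureHeadSupply(p_head=60.0)
        with pytest.raises(NumericalError):
            calibrate_rest(small_grid, params, supply, target_inflow=1e9)


class TestValidation:
    def test_grid_and_param_invariants(self):
        with pytest.raises(ValidationError):
            DarcyGrid(1, 4, 4, 1e-3)
        with pytest.raises(ValidationError):
            DarcyGrid(4, 4, 4, -1e-3)
        with pytest.raises(ValidationError):
            DarcyParams(gamma=0.0)
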