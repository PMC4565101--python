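"""Conduction solver: discretization, nonlinearity, and conservation.

Solver tests run on deliberately small grids (coarse spacing or reduced
boxes) so the whole suite stays fast; grid-convergence behavior is checked
separately.
"""

import math

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from ectplan import (
    ElectrodeConfig,
    NeedleElectrode,
    PairExcitation,
    SigmaModel,
    SolverSettings,
    TissueModel,
    assemble_system,
    compute_current,
    make_symmetric_config,
    rasterize,
    sigma_update,
    solve_pair,
)

FAST = SolverSettings(cg_rtol=1e-10)
FAST_CLOSED = SolverSettings(cg_rtol=1e-10, robin_face=None)


@pytest.fixture(scope="module")
def small_grid():
    """Symmetric five-needle layout on a coarse (2.5 mm) grid."""
    tissue = TissueModel()
    return rasterize(tissue, make_symmetric_config(tissue), spacing=0.25)


@pytest.fixture(scope="module")
def pair12(small_grid):
    return solve_pair(small_grid, PairExcitation(1, 2, 2000.0), SigmaModel(), FAST)


class TestSigmaModel:
    def test_band_multipliers(self):
        sm = SigmaModel()
        fields = np.array([0.0, 300.0, 400.0, 799.9, 800.0, 2000.0])
        assert list(sm.multipliers(fields)) == [1.0, 1.0, 2.5, 2.5, 3.5, 3.5]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            SigmaModel(E_rev=800, E_irr=400)
        with pytest.raises(ValueError):
            SigmaModel(f_rev=3.5, f_irr=2.5)

    def test_update_keeps_baseline_below_threshold(self, small_grid):
        field = np.full(small_grid.shape, 300.0)
        out = sigma_update(field, small_grid, SigmaModel())
        tumor = small_grid.tumor_mask
        assert np.allclose(out[tumor], 0.55)

    def test_update_scales_by_band(self, small_grid):
        sm = SigmaModel()
        hot = np.full(small_grid.shape, 900.0)
        out = sigma_update(hot, small_grid, sm)
        tumor = small_grid.tumor_mask
        assert np.allclose(out[tumor], 0.55 * sm.f_irr)

    def test_update_idempotent_and_electrodes_untouched(self, small_grid):
        field = np.full(small_grid.shape, 500.0)
        once = sigma_update(field, small_grid, SigmaModel())
        assert np.array_equal(once, sigma_update(field, small_grid, SigmaModel()))
        emask = small_grid.label >= 100
        assert np.array_equal(once[emask], small_grid.baseline_sigma[emask])

    def test_unit_multipliers_recover_baseline(self, small_grid):
        field = np.full(small_grid.shape, 5000.0)
        out = sigma_update(field, small_grid, SigmaModel(f_rev=1.0, f_irr=1.0))
        assert np.array_equal(out, small_grid.baseline_sigma)


class TestAssembly:
    def test_matrix_spd_after_elimination(self, small_grid):
        A, b, _ = assemble_system(small_grid, small_grid.baseline_sigma,
                                  PairExcitation(1, 2, 100.0), FAST)
        assert (A != A.T).nnz == 0
        # smallest eigenvalue of the reduced system is positive
        lmin = spla.eigsh(A.asfptype(), k=1, which="SA", return_eigenvectors=False,
                          maxiter=5000, tol=1e-6)[0]
        assert lmin > 0

    def test_insulated_domain_without_electrodes_rejected(self):
        # no Dirichlet voxels anywhere: the all-insulating problem only has
        # the constant null-space solution and must be refused up front
        tissue = TissueModel()
        grid = rasterize(tissue, None, spacing=0.5)
        with pytest.raises(ValueError, match="not present"):
            assemble_system(grid, grid.baseline_sigma, PairExcitation(1, 2, 0.0),
                            SolverSettings(robin_face=None))

    def test_two_plate_problem_linear_potential(self):
        # quasi-1D: two full-width plates realized as rows of needles is
        # overkill; instead check the analytic two-needle mid-plane symmetry
        tissue = TissueModel(box_side=6.0, tumor_semiaxes=(1e-3,) * 3,
                             sigma_tumor0=0.04, sigma_background0=0.04)
        cfg = ElectrodeConfig((
            NeedleElectrode(1, (-1.0, 0, 3.0), active_length=6.0),
            NeedleElectrode(2, (1.0, 0, 3.0), active_length=6.0),
        ))
        grid = rasterize(tissue, cfg, 0.2)
        sol = solve_pair(grid, PairExcitation(1, 2, 100.0), SigmaModel(enabled=False),
                         FAST_CLOSED)
        # anti-symmetry plane between the electrodes sits at V/2
        mid = sol.potential[grid.shape[0] // 2, :, :]
        assert np.allclose(mid, 50.0, atol=0.5)


class TestSolvePair:
    def test_zero_voltage_gives_null_solution(self, small_grid):
        sol = solve_pair(small_grid, PairExcitation(1, 2, 0.0), SigmaModel(), FAST)
        assert not sol.potential.any()
        assert not sol.field_magnitude.any()
        assert all(v == 0 for v in sol.currents.values())

    def test_charge_conservation(self, pair12):
        assert pair12.conservation_error <= 1e-3

    def test_source_positive_sink_negative(self, pair12):
        assert pair12.currents[1] > 0
        assert pair12.currents[2] < 0

    def test_floating_electrodes_carry_no_net_current(self, pair12):
        for eid in (3, 4, 5):
            assert abs(pair12.currents[eid]) <= 1e-3 * pair12.currents[1]

    def test_floating_potentials_between_rails(self, pair12):
        for v in pair12.floating_potentials.values():
            assert 0.0 < v < 2000.0

    def test_field_and_sigma_invariants(self, pair12, small_grid):
        assert (pair12.field_magnitude >= 0).all()
        assert (pair12.sigma_final >= small_grid.baseline_sigma - 1e-12).all()

    def test_linearity_without_electroporation(self, small_grid):
        off = SigmaModel(enabled=False)
        a = solve_pair(small_grid, PairExcitation(1, 2, 1000.0), off, FAST)
        b = solve_pair(small_grid, PairExcitation(1, 2, 2000.0), off, FAST)
        assert b.currents[1] == pytest.approx(2 * a.currents[1], rel=1e-9)
        assert np.allclose(b.potential, 2 * a.potential, atol=1e-6)

    def test_electroporation_never_decreases_current(self, small_grid):
        off = solve_pair(small_grid, PairExcitation(1, 2, 2000.0),
                         SigmaModel(enabled=False), FAST)
        on = solve_pair(small_grid, PairExcitation(1, 2, 2000.0), SigmaModel(), FAST)
        assert on.currents[1] >= off.currents[1]

    def test_reciprocity_under_source_sink_swap(self, small_grid):
        fwd = solve_pair(small_grid, PairExcitation(1, 3, 800.0),
                         SigmaModel(enabled=False), FAST_CLOSED)
        rev = solve_pair(small_grid, PairExcitation(3, 1, 800.0),
                         SigmaModel(enabled=False), FAST_CLOSED)
        assert rev.currents[3] == pytest.approx(fwd.currents[1], rel=1e-6)
        # potentials mirror around V/2 (sum of both solves is constant 800)
        assert np.allclose(fwd.potential + rev.potential, 800.0, atol=1e-3)

    def test_convergence_log_records_iterations(self, pair12):
        assert pair12.converged
        assert len(pair12.convergence_log) == pair12.iterations
        assert pair12.convergence_log[-1]["band_change_fraction"] <= 1e-3


class TestOracle:
    def test_parallel_cylinder_resistance(self):
        """Two full-height rods in a uniform box against the closed form
        I = V pi sigma L / acosh(d / 2a) for parallel cylinders."""
        V, d_cm, a_mm, sigma = 100.0, 2.0, 0.6, 0.04
        box = 8.0
        tissue = TissueModel(box_side=box, tumor_semiaxes=(1e-3,) * 3,
                             sigma_tumor0=sigma, sigma_background0=sigma)
        cfg = ElectrodeConfig((
            NeedleElectrode(1, (-d_cm / 2, 0, box / 2), active_length=box),
            NeedleElectrode(2, (d_cm / 2, 0, box / 2), active_length=box),
        ))
        grid = rasterize(tissue, cfg, 0.2)
        sol = solve_pair(grid, PairExcitation(1, 2, V), SigmaModel(enabled=False),
                         FAST_CLOSED)
        L = box / 100.0
        I_exact = V * math.pi * sigma * L / math.acosh(d_cm / 2 / (a_mm / 10))
        assert sol.currents[1] == pytest.approx(I_exact, rel=0.10)

    def test_current_grid_convergence(self):
        """Pair current changes by <= 5% when the spacing is halved."""
        tissue = TissueModel()
        cfg = make_symmetric_config(tissue)
        currents = []
        for h in (0.25, 0.125):
            grid = rasterize(tissue, cfg, h)
            sol = solve_pair(grid, PairExcitation(5, 1, 1400.0),
                             SigmaModel(enabled=False), FAST)
            currents.append(sol.currents[5])
        assert abs(currents[1] - currents[0]) / currents[1] <= 0.05


class TestComputeCurrent:
    def test_matches_stored_current(self, small_grid, pair12):
        recomputed = compute_current(pair12, small_grid, 1, FAST)
        assert recomputed == pytest.approx(pair12.currents[1], rel=1e-9)

    def test_missing_electrode_rejected(self, small_grid, pair12):
        with pytest.raises(KeyError):
            small_grid.config.get(9)
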