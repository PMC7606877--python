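"""Population-balance solver: moments, schemes, conservation, convergence."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stempop.analytic import pscd_total_alp, pscd_total_cells
from stempop.balance_solver import (
    ALPDistribution,
    MomentSeries,
    compute_moments,
    gamma_distribution,
    make_grid,
    moment_rates,
    solve_population_balance,
)
from stempop.model_core import (
    DivisionMode,
    ModelSpec,
    PSCDParams,
    conserved_model,
    pscd_model,
)


def null_model(**kw):
    return ModelSpec(division_rate=0.0, **kw)


class TestComputeMoments:
    def test_zero_density(self):
        grid = np.linspace(0, 1, 11)
        assert compute_moments(ALPDistribution(grid, np.zeros(11))) == (0.0, 0.0)

    def test_uniform_density(self):
        grid = np.linspace(0, 1, 2001)
        N, Phi = compute_moments(ALPDistribution(grid, np.ones(2001)))
        da = grid[1] - grid[0]
        assert N == pytest.approx(1.0, abs=10 * da**2)
        assert Phi == pytest.approx(0.5, abs=10 * da**2)

    def test_narrow_gaussian_unit_mass(self):
        grid = np.linspace(0, 4, 4001)
        sig = 0.05
        dens = np.exp(-((grid - 2.0) ** 2) / (2 * sig**2)) / (sig * math.sqrt(2 * math.pi))
        N, Phi = compute_moments(ALPDistribution(grid, dens))
        assert N == pytest.approx(1.0, rel=1e-6)
        assert Phi == pytest.approx(2.0, rel=1e-6)

    def test_nan_density_rejected(self):
        grid = np.linspace(0, 1, 11)
        dist = ALPDistribution(grid, np.ones(11))
        dist.density = dist.density.copy()
        dist.density[3] = np.nan
        with pytest.raises(ValueError):
            compute_moments(dist)


class TestDistributionInvariants:
    def test_negative_density_beyond_tolerance_rejected(self):
        grid = np.linspace(0, 1, 11)
        with pytest.raises(ValueError):
            ALPDistribution(grid, np.full(11, -1e-6))

    def test_tiny_negative_density_clipped(self):
        grid = np.linspace(0, 1, 11)
        d = ALPDistribution(grid, np.full(11, -1e-13))
        assert np.all(d.density >= 0)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            ALPDistribution(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_moment_series_requires_equal_finite_nonnegative(self):
        with pytest.raises(ValueError):
            MomentSeries(np.arange(3.0), np.arange(3.0), np.arange(2.0))
        with pytest.raises(ValueError):
            MomentSeries(np.arange(3.0), np.array([1.0, -1.0, 1.0]), np.ones(3))


class TestEvolution:
    def test_all_zero_model_is_identity(self):
        grid = make_grid(10.0, 101)
        init = gamma_distribution(50.0, 2.0, grid)
        snaps, mom = solve_population_balance(null_model(), init, 0.0, 5.0, 50)
        np.testing.assert_allclose(snaps[-1].density, init.density, atol=1e-12)
        np.testing.assert_allclose(mom.N, mom.N[0], rtol=1e-12)

    def test_symmetric_division_matches_scalar_ode_oracle(self):
        """Pure non-conserved division: N(t) must follow dN/dt = k N."""
        k = 0.35
        model = ModelSpec(division_rate=k)
        grid = make_grid(15.0, 151)
        init = gamma_distribution(100.0, 2.0, grid)
        _, mom = solve_population_balance(model, init, 0.0, 4.0, 800)
        oracle = solve_ivp(lambda t, y: k * y, (0.0, 4.0), [100.0],
                           t_eval=[4.0], rtol=1e-10, atol=1e-12)
        assert mom.N[-1] == pytest.approx(oracle.y[0, -1], rel=5e-3)
        # Phi grows with the same factor (activities unchanged by copying)
        assert mom.Phi[-1] / mom.Phi[0] == pytest.approx(mom.N[-1] / mom.N[0],
                                                         rel=1e-10)

    @pytest.mark.parametrize("shape", [2.0, 5.0])
    def test_pscd_matches_closed_forms_for_any_initial_shape(self, shape):
        """Solver moments track N̄0·t² and Φ̄0·t²·e^{−d0 t} within 1%."""
        d0 = 1.0 / 5.84
        t0 = 7.0
        model = pscd_model(d0)
        N0, mean_a = 26215.0, 2.0
        params = PSCDParams(N_bar0=N0 / t0**2,
                            Phi_bar0=N0 * mean_a * math.exp(d0 * t0) / t0**2,
                            d0=d0)
        grid = make_grid(12.0 * mean_a, 400, spacing="geometric")
        init = gamma_distribution(N0, mean_a, grid, shape=shape, time=t0)
        _, mom = solve_population_balance(model, init, t0, 28.0, 2000,
                                          scheme="heun", flux="muscl")
        for day in (7.0, 14.0, 21.0, 28.0):
            i = int(np.argmin(np.abs(mom.times - day)))
            assert mom.N[i] == pytest.approx(pscd_total_cells(day, params),
                                             rel=0.01)
            assert mom.Phi[i] == pytest.approx(pscd_total_alp(day, params),
                                               rel=0.01)

    def test_conserved_division_preserves_total_alp(self):
        """Activity-conserving divisions: Φ constant to 0.1%, N non-decreasing."""
        model = conserved_model(0.05)
        grid = make_grid(30.0, 240)
        init = gamma_distribution(100.0, 2.0, grid)
        _, mom = solve_population_balance(model, init, 0.0, 28.0, 600)
        assert np.max(np.abs(mom.Phi / mom.Phi[0] - 1.0)) < 1e-3
        assert np.all(np.diff(mom.N) >= -1e-10 * mom.N[0])

    def test_degradation_advection_conserves_cell_number(self):
        """d_o(a) = d0·a vanishes at a=0: no cell flux out of the domain."""
        d0 = 0.3
        model = ModelSpec(division_rate=0.0,
                          degradation_flux=lambda a: d0 * np.asarray(a))
        grid = make_grid(20.0, 301)
        init = gamma_distribution(80.0, 2.0, grid)
        _, mom = solve_population_balance(model, init, 0.0, 3.0, 600)
        assert mom.N[-1] == pytest.approx(mom.N[0], rel=1e-6)
        assert mom.boundary_loss[-1] == 0.0

    def test_cfl_violation_refused_with_stable_step(self):
        model = pscd_model(1.0)
        grid = make_grid(20.0, 400)
        init = gamma_distribution(10.0, 2.0, grid, time=1.0)
        with pytest.raises(ValueError, match="CFL"):
            solve_population_balance(model, init, 1.0, 10.0, 5)

    def test_negative_rate_model_rejected(self):
        model = ModelSpec(division_rate=1.0,
                          differentiation_rate=lambda a: -np.ones_like(a))
        grid = make_grid(10.0, 51)
        init = gamma_distribution(10.0, 2.0, grid)
        with pytest.raises(ValueError):
            solve_population_balance(model, init, 0.0, 1.0, 10)


class TestMomentRates:
    def test_all_zero_model(self):
        grid = make_grid(10.0, 101)
        dist = gamma_distribution(50.0, 2.0, grid)
        assert moment_rates(null_model(), dist) == (0.0, 0.0)

    def test_iscd_reduced_form(self):
        """Constant division k and removal k_f give (k̄N, k̄Φ), k̄ = k − k_f."""
        k, k_f = 0.4, 0.1
        model = ModelSpec(division_rate=k,
                          differentiation_rate=lambda a: np.full_like(
                              np.asarray(a, dtype=float), k_f))
        grid = make_grid(12.0, 401)
        dist = gamma_distribution(60.0, 1.5, grid)
        N, Phi = compute_moments(dist)
        dN, dPhi = moment_rates(model, dist)
        assert dN == pytest.approx((k - k_f) * N, rel=1e-9)
        assert dPhi == pytest.approx((k - k_f) * Phi, rel=1e-9)

    def test_pscd_alp_rate_matches_closed_form(self):
        """d_o(a)=d0·a integrates to d0·Φ: dΦ/dt = (2/t − d0)·Φ."""
        d0 = 1.0 / 5.84
        model = pscd_model(d0)
        grid = make_grid(12.0, 401)
        dist = gamma_distribution(60.0, 1.5, grid, time=7.0)
        _, Phi = compute_moments(dist)
        _, dPhi = moment_rates(model, dist)
        assert dPhi == pytest.approx((2.0 / 7.0 - d0) * Phi, rel=1e-6)

    def test_conserved_constant_kernel_rates(self):
        """For k_d ≡ c: dN/dt = c·Φ/2 and dΦ/dt = 0 (exact identities)."""
        c = 0.08
        model = conserved_model(c)
        grid = make_grid(40.0, 401)
        dist = gamma_distribution(100.0, 2.0, grid)
        _, Phi = compute_moments(dist)
        dN, dPhi = moment_rates(model, dist)
        assert dN == pytest.approx(0.5 * c * Phi, rel=5e-3)
        assert abs(dPhi) < 1e-10 * Phi

    def test_solver_moment_derivative_consistent_with_rates(self):
        """Finite-difference dN/dt, dΦ/dt of the solver agree with the
        balance-relation quadratures to first order in the step.

        d0 = 0.5 keeps dΦ/dt = (2/t − d0)Φ bounded away from zero on the
        integration window, so relative comparison is well-posed."""
        d0 = 0.5
        model = pscd_model(d0)
        grid = make_grid(25.0, 301, spacing="geometric")
        init = gamma_distribution(40.0, 2.0, grid, time=5.0)
        n_steps = 400
        snaps, mom = solve_population_balance(model, init, 5.0, 9.0, n_steps,
                                              scheme="heun", flux="muscl",
                                              n_snapshots=5)
        dt = (9.0 - 5.0) / n_steps
        for snap in snaps[1:-1]:
            i = int(np.argmin(np.abs(mom.times - snap.time)))
            fd_N = (mom.N[i + 1] - mom.N[i - 1]) / (2 * dt)
            fd_Phi = (mom.Phi[i + 1] - mom.Phi[i - 1]) / (2 * dt)
            dN, dPhi = moment_rates(model, snap)
            assert fd_N == pytest.approx(dN, rel=0.02)
            assert fd_Phi == pytest.approx(dPhi, rel=0.02)


def test_grid_refinement_reduces_moment_error_first_order():
    """Halving Δa and Δt shrinks the Φ error by at least 1.8x (upwind)."""
    d0 = 0.2
    model = pscd_model(d0)
    t0, t1 = 1.0, 3.0
    params = PSCDParams(N_bar0=100.0,
                        Phi_bar0=100.0 * 2.0 * math.exp(d0 * t0) / t0**2,
                        d0=d0)
    errs = []
    for G, steps in [(100, 400), (200, 800)]:
        grid = make_grid(20.0, G)
        init = gamma_distribution(100.0, 2.0, grid, time=t0)
        _, mom = solve_population_balance(model, init, t0, t1, steps)
        exact = pscd_total_alp(t1, params)
        errs.append(abs(mom.Phi[-1] - exact) / exact)
    assert errs[0] / errs[1] >= 1.8
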