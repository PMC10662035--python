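"""Simulator building blocks: sponge, vertical solve, bottom source,
shear-stress averaging, seagrass stepping, hydrodynamic stepping."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import solve_banded

from braggrass.braggsim import (
    SimulationGrid,
    averaged_shear_perturbation,
    bottom_source,
    build_sponge,
    dtn_map,
    make_grid,
    seagrass_rhs,
    step_hydrodynamics,
    step_seagrass,
    wave_energy,
)
from braggrass.equilibria import (
    default_seagrass_params,
    default_wave_parameters,
    uniform_equilibrium,
)

G = 9.81


def fd_vertical_oracle(phis_hat, wb_hat, H0, k, Nz=2000):
    """Independent second-order finite-difference solve of the mode-reduced
    Laplace problem phi'' = k^2 phi on [-H0, 0] with phi(0) = phis and
    phi'(-H0) = wb; banded tridiagonal-plus-corners system per mode."""
    dz = H0 / Nz
    ws = np.zeros_like(phis_hat)
    phib = np.zeros_like(phis_hat)
    for m, (p, w, kk) in enumerate(zip(phis_hat, wb_hat, np.abs(k))):
        A = np.zeros((5, Nz + 1), complex)
        rhs = np.zeros(Nz + 1, complex)
        A[2, 1:Nz] = -2.0 - (kk * dz) ** 2
        A[1, 2:Nz + 1] = 1.0
        A[3, 0:Nz - 1] = 1.0
        A[2, 0] = -3 / (2 * dz)
        A[1, 1] = 4 / (2 * dz)
        A[0, 2] = -1 / (2 * dz)
        rhs[0] = w
        A[2, Nz] = 1.0
        rhs[Nz] = p
        phi = solve_banded((2, 2), A, rhs)
        ws[m] = (3 * phi[Nz] - 4 * phi[Nz - 1] + phi[Nz - 2]) / (2 * dz)
        phib[m] = phi[0]
    return ws, phib, 1j * k * phib


class TestSponge:
    def test_profile_endpoints_and_interior(self):
        grid = make_grid(50.0, 6, 2, 32)
        sp = build_sponge(grid, gamma_max=1.5, exponent=2)
        assert np.all(sp.gamma[grid.interior_mask] == 0.0)
        assert sp.gamma[0] == pytest.approx(1.5, rel=1e-6)  # x = -L edge
        # continuous first derivative at the border for a quadratic ramp
        dgam = np.diff(sp.gamma) / grid.dx
        border = np.argmax(sp.gamma[: grid.Nx // 2] == 0)
        assert abs(dgam[border - 1]) < 3 * 1.5 / (2 * 50.0 / grid.dx)

    def test_monotone_toward_boundaries(self):
        grid = make_grid(40.0, 4, 1.5, 32)
        sp = build_sponge(grid, 2.0, 3.0)
        left = sp.gamma[: grid.Nx // 2]
        assert np.all(np.diff(left) <= 1e-15)

    def test_invalid_arguments(self):
        grid = make_grid(40.0, 4, 1.5, 32)
        with pytest.raises(ValueError):
            build_sponge(grid, 1.0, exponent=1.0)
        flat = SimulationGrid(L=100.0, dL=0.0, Nx=64)
        with pytest.raises(ValueError):
            build_sponge(flat, 1.0)

    def test_pulse_absorbed_below_tolerance(self):
        # a rightward monochromatic packet enters the sponge and must not
        # come back above 1e-3 of its incident amplitude
        from braggrass.linear_wave_core import solve_dispersion
        T, H0 = 8.0, 3.0
        om = 2 * math.pi / T
        ds = solve_dispersion(T, H0)
        kap, lam = ds.kappa, ds.lam
        grid = make_grid(lam, 10, 2, 64)
        sponge = build_sponge(grid, om, 2.0)  # default gamma_max = sigma
        x = grid.x
        env = np.exp(-(x / (2 * lam)) ** 2)
        eta = 0.01 * env * np.cos(kap * x)
        phis = 0.01 * (G / om) * env * np.sin(kap * x)
        incident = np.abs(eta[grid.interior_mask]).max()
        cg = 0.5 * om / kap * (1 + 2 * kap * H0 / math.sinh(2 * kap * H0))
        dt = T / 128
        t = 0.0
        for _ in range(int(2.5 * grid.L / cg / dt)):
            eta, phis = step_hydrodynamics(eta, phis, t, dt, G, sponge.gamma,
                                           H0, grid.k, None)
            t += dt
        returned = np.abs(eta[grid.interior_mask & (x < 0)]).max()
        assert returned / incident < 1e-3


class TestDtnMap:
    def setup_method(self):
        self.Nx, self.H0, self.Lx = 16, 3.0, 60.0
        self.k = 2 * np.pi * np.fft.rfftfreq(self.Nx, d=self.Lx / self.Nx)

    def test_surface_dirichlet_to_neumann_single_mode(self):
        phis_hat = np.zeros(len(self.k), complex)
        phis_hat[3] = 1.0
        ws, _, _ = dtn_map(phis_hat, np.zeros_like(phis_hat), self.H0, self.k)
        kk = self.k[3]
        assert ws[3] == pytest.approx(kk * math.tanh(kk * self.H0), rel=1e-12)

    def test_bottom_forced_single_mode(self):
        wb_hat = np.zeros(len(self.k), complex)
        wb_hat[4] = 2.0
        ws, phib, _ = dtn_map(np.zeros_like(wb_hat), wb_hat, self.H0, self.k)
        kk = self.k[4]
        assert ws[4] == pytest.approx(2.0 / math.cosh(kk * self.H0), rel=1e-12)
        assert phib[4] == pytest.approx(-2.0 * math.tanh(kk * self.H0) / kk,
                                        rel=1e-12)

    def test_mean_mode_limits(self):
        phis_hat = np.array([1.5 + 0j]); wb_hat = np.array([0.5 + 0j])
        ws, phib, ub = dtn_map(phis_hat, wb_hat, self.H0, np.array([0.0]))
        assert ws[0] == pytest.approx(0.5)
        assert phib[0] == pytest.approx(1.5 - 0.5 * self.H0)
        assert ub[0] == 0.0

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(42)
        phis_hat = np.fft.rfft(rng.normal(size=self.Nx))
        wb_hat = np.fft.rfft(0.1 * rng.normal(size=self.Nx))
        got = dtn_map(phis_hat, wb_hat, self.H0, self.k)
        want = fd_vertical_oracle(phis_hat, wb_hat, self.H0, self.k)
        for g_, w_ in zip(got, want):
            assert np.abs(g_ - w_).max() / np.abs(g_).max() < 1e-4

    def test_nan_input_rejected(self):
        bad = np.full(len(self.k), np.nan, complex)
        with pytest.raises(FloatingPointError, match="dtn_map"):
            dtn_map(bad, np.zeros_like(bad), self.H0, self.k)


class TestBottomSource:
    def setup_method(self):
        self.grid = make_grid(50.0, 8, 2, 32)
        self.k = self.grid.k
        self.kap = 2 * math.pi / 50.0

    def test_no_vegetation_no_source(self):
        z = np.zeros(self.grid.Nx)
        u0b = np.cos(self.kap * self.grid.x)
        assert np.all(bottom_source(z, z, u0b, 1.4, self.k) == 0.0)

    def test_bragg_sidebands_of_static_pattern(self):
        # n1 at 2*kappa against u0b at kappa: flux derivative lives at
        # kappa and 3*kappa (product-to-sum)
        x = self.grid.x
        n1 = 0.01 * np.cos(2 * self.kap * x)
        u0b = 0.2 * np.cos(self.kap * x)
        wb = bottom_source(n1, np.zeros_like(n1), u0b, 1.4, self.k)
        amp = np.abs(np.fft.rfft(wb))
        khat = self.k
        for mult, present in ((1, True), (2, False), (3, True)):
            b = np.argmin(np.abs(khat - mult * self.kap))
            if present:
                assert amp[b] > 100 * np.median(amp)
            else:
                assert amp[b] < 1e-8 * amp.max()

    def test_flux_term_integrates_to_zero(self):
        rng = np.random.default_rng(1)
        n1 = rng.normal(size=self.grid.Nx)
        dn1 = rng.normal(size=self.grid.Nx)
        u0b = rng.normal(size=self.grid.Nx)
        wb = bottom_source(n1, dn1, u0b, 0.7, self.k)
        # domain integral reduces to the moving-bed part: s * d/dt int n1 dx
        assert np.mean(wb) == pytest.approx(0.7 * np.mean(dn1), rel=1e-10)


class TestAveragedShear:
    def test_zero_perturbation_velocity(self):
        buf = np.zeros((128, 64))
        tau = averaged_shear_perturbation(buf, True, 1025.0, 0.05)
        assert np.all(tau == 0.0)

    def test_proportional_perturbation_doubles_stress(self):
        # u1b = eps*u0b gives tau_b1 = 2*eps*tau_b0
        eps, U = 0.01, 0.3
        t = np.linspace(0, 8.0, 128, endpoint=False)
        u0b = U * np.cos(2 * np.pi * t / 8.0)
        buf = (u0b * eps * u0b)[:, None] * np.ones((1, 4))
        tau = averaged_shear_perturbation(buf, True, 1025.0, 0.05)
        tau_b0 = 0.5 * 1025.0 * 0.05 * U**2
        np.testing.assert_allclose(tau, 2 * eps * tau_b0, rtol=1e-12)

    def test_standing_wave_gives_2k_pattern(self):
        # closed-form trailing-period mean of cos(kx)cos(st) * U cos(kx-st)
        kap, U, B = 0.1, 0.3, 0.05
        x = np.linspace(0, 4 * np.pi / kap, 256, endpoint=False)
        t = np.linspace(0, 8.0, 128, endpoint=False)
        sig = 2 * np.pi / 8.0
        u0b = U * np.cos(kap * x[None, :] - sig * t[:, None])
        u1b = B * np.cos(kap * x[None, :]) * np.cos(sig * t[:, None])
        tau = averaged_shear_perturbation(u0b * u1b, True, 1025.0, 0.05)
        expected = 2 * 1025.0 * 0.05 * (U * B / 4) * (1 + np.cos(2 * kap * x))
        np.testing.assert_allclose(tau, expected, atol=1e-12 + 1e-9 * abs(expected).max())

    def test_insufficient_history_rejected(self):
        with pytest.raises(RuntimeError, match="spin"):
            averaged_shear_perturbation(np.zeros((4, 4)), False, 1025.0, 0.05)


class TestStepSeagrass:
    def setup_method(self):
        self.wp = default_wave_parameters()
        self.sp = default_seagrass_params()
        self.basic = uniform_equilibrium(self.wp.a, self.wp.T, self.wp, self.sp)
        self.grid = make_grid(2 * math.pi / self.basic.kappa, 8, 2, 32)
        self.k = self.grid.k

    def test_equilibrium_is_fixed_point(self):
        n1 = np.zeros(self.grid.Nx)
        tau = np.zeros(self.grid.Nx)
        out = step_seagrass(n1, tau, self.basic, self.sp, 0.01, self.k)
        assert np.all(out == 0.0)

    def test_uniform_perturbation_decay_rate(self):
        # linearized rate about the vegetated state: -omega0+2 alpha n0-3 beta n0^2
        n0 = self.basic.n0
        lin = -self.basic.omega0 + 2 * self.sp.alpha * n0 - 3 * self.sp.beta * n0**2
        assert lin < 0
        n1 = np.full(self.grid.Nx, 1e-6)
        tau = np.zeros(self.grid.Nx)
        dtau = 1e-3
        out = n1.copy()
        for _ in range(1000):
            out = step_seagrass(out, tau, self.basic, self.sp, dtau, self.k)
        measured = math.log(out[0] / n1[0]) / (1000 * dtau)
        assert measured == pytest.approx(lin, rel=1e-3)

    def test_linear_response_to_sinusoidal_stress(self):
        # steady forced amplitude = omega_c*n0*|tau| / (decay + delta*(2k)^2)
        kap2 = 2 * self.basic.kappa
        kq = round(kap2 * 2 * self.grid.L / (2 * np.pi)) * 2 * np.pi / (2 * self.grid.L)
        tau = 1e-4 * np.cos(kq * self.grid.x)
        n1 = np.zeros(self.grid.Nx)
        dtau = 5e-3
        for _ in range(20000):
            n1 = step_seagrass(n1, tau, self.basic, self.sp, dtau, self.k)
        n0 = self.basic.n0
        decay = self.basic.omega0 - 2 * self.sp.alpha * n0 + 3 * self.sp.beta * n0**2
        expected = self.sp.omega_c * n0 * 1e-4 / (decay + self.sp.delta * kq**2)
        assert np.abs(n1).max() == pytest.approx(abs(expected), rel=1e-3)

    def test_total_density_clipped_nonnegative(self):
        n1 = np.full(self.grid.Nx, -10.0)
        tau = np.zeros(self.grid.Nx)
        with pytest.warns(UserWarning, match="bare"):
            out = step_seagrass(n1, tau, self.basic, self.sp, 0.1, self.k,
                                self.grid.interior_mask)
        assert np.all(out >= -self.basic.n0 - 1e-15)


class TestStepHydrodynamics:
    def test_quiescent_state_stays_zero(self):
        grid = make_grid(50.0, 6, 2, 32)
        z = np.zeros(grid.Nx)
        eta, phis = z.copy(), z.copy()
        gamma = build_sponge(grid, 1.0).gamma
        for i in range(50):
            eta, phis = step_hydrodynamics(eta, phis, i * 0.05, 0.05, G, gamma,
                                           3.0, grid.k, None)
        assert np.all(eta == 0.0) and np.all(phis == 0.0)

    def test_free_mode_oscillates_at_dispersion_frequency(self):
        H0 = 3.0
        grid = SimulationGrid(L=100.0, dL=0.0, Nx=256)
        km = 2 * np.pi * 5 / (2 * grid.L)
        om = math.sqrt(G * km * math.tanh(km * H0))
        T = 2 * np.pi / om
        dt = T / 128
        eta = np.zeros(grid.Nx)
        phis = np.cos(km * grid.x)
        gamma = np.zeros(grid.Nx)
        proj = []
        t = 0.0
        for _ in range(128 * 10):
            eta, phis = step_hydrodynamics(eta, phis, t, dt, G, gamma, H0,
                                           grid.k, None)
            t += dt
            proj.append(float(np.sum(phis * np.cos(km * grid.x))))
        proj = np.asarray(proj)
        idx = np.nonzero(np.diff(np.sign(proj)))[0]
        tc = [(i + 1) * dt - proj[i] * dt / (proj[i + 1] - proj[i]) for i in idx]
        om_meas = 2 * np.pi / (2 * np.mean(np.diff(tc)))
        assert om_meas == pytest.approx(om, rel=1e-4)

    def test_energy_nonincreasing_with_damping(self):
        grid = make_grid(50.0, 6, 2, 32)
        sponge = build_sponge(grid, 1.0)
        rng = np.random.default_rng(0)
        eta = 0.01 * rng.normal(size=grid.Nx)
        phis = 0.01 * rng.normal(size=grid.Nx)
        E = [wave_energy(eta, phis, 3.0, grid.k, G)]
        t = 0.0
        for _ in range(200):
            eta, phis = step_hydrodynamics(eta, phis, t, 0.05, G, sponge.gamma,
                                           3.0, grid.k, None)
            t += 0.05
            E.append(wave_energy(eta, phis, 3.0, grid.k, G))
        E = np.asarray(E)
        assert np.all(np.diff(E) <= 1e-12 * E[0])


class TestGrid:
    def test_geometry(self):
        grid = make_grid(47.0, 20, 2, 32)
        assert grid.Nx % 2 == 0
        assert 2 * (grid.L - grid.dL) == pytest.approx(20 * 47.0)
        assert grid.dL == pytest.approx(2 * 47.0)

    def test_resolution_floor_enforced(self):
        with pytest.raises(ValueError, match="32"):
            make_grid(47.0, 10, 2, 16)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            SimulationGrid(L=10.0, dL=12.0, Nx=64)
        with pytest.raises(ValueError):
            SimulationGrid(L=10.0, dL=1.0, Nx=63)
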