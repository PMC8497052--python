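"""Spatial integrator, initial conditions, wavelength detection, linear algebra."""

import numpy as np
import pytest

from dryveg import ModelParams, build_trait_grid
from dryveg.model import CommunityState, bare_soil_state
from dryveg.spatial import (
    _jac_blocks,
    _jac_flat,
    composite_state,
    integrate,
    make_initial,
    pattern_wavelength,
    single_group_grid,
)
from dryveg.steady import PeriodicBlockTridiagLU, settle


class TestBlockSolver:
    @pytest.mark.parametrize("N, nx", [(4, 5), (12, 16), (3, 32)])
    def test_matches_general_sparse_solve(self, N, nx):
        from scipy import sparse
        from scipy.sparse.linalg import spsolve

        p = ModelParams(P=100.0, N=max(N, 2))
        grid = build_trait_grid(N, p) if N >= 2 else None
        rng = np.random.default_rng(7)
        y = np.abs(rng.normal(1.0, 0.3, nx * (N + 2)))
        dx, dt = 3.0, 0.7
        A = _jac_flat(y, grid, p, nx, dx)
        M = (sparse.eye(nx * (N + 2), format="csc") - dt * A).tocsc()
        diag, off = _jac_blocks(y, grid, p, nx, dx)
        diag = -dt * diag
        idx = np.arange(N + 2)
        diag[:, idx, idx] += 1.0
        solver = PeriodicBlockTridiagLU(diag, -dt * off)
        b = rng.normal(size=(nx, N + 2))
        x = solver.solve(b)
        x_ref = spsolve(M, b.ravel()).reshape(nx, N + 2)
        assert np.abs(x - x_ref).max() < 1e-10 * max(1.0, np.abs(x_ref).max())

    def test_jacobian_matches_finite_differences(self):
        p = ModelParams(P=90.0, N=6)
        grid = build_trait_grid(6, p)
        nx, dx = 8, 4.0
        rng = np.random.default_rng(3)
        y = np.abs(rng.normal(0.5, 0.2, nx * 8))
        from dryveg.spatial import _rhs_flat

        J = _jac_flat(y, grid, p, nx, dx).toarray()
        Jfd = np.empty_like(J)
        f0 = _rhs_flat(y, grid, p, nx, dx)
        for j in range(y.size):
            e = np.zeros_like(y)
            e[j] = 1e-7
            Jfd[:, j] = (_rhs_flat(y + e, grid, p, nx, dx) - f0) / 1e-7
        assert np.abs(J - Jfd).max() < 1e-4 * max(1.0, np.abs(Jfd).max())


class TestMakeInitial:
    def test_bare_soil_is_the_analytic_fixed_point(self, params):
        grid = build_trait_grid(8, params)
        p = params.replace(P=80.0)
        state = make_initial("bare_soil", grid, p, nx=16, length=100.0)
        W0, H0 = bare_soil_state(p)
        assert state.B.max() == 0.0
        assert state.W == pytest.approx(np.full(16, 20.0))
        assert state.H == pytest.approx(np.full(16, 200.0))
        assert (W0, H0) == pytest.approx((20.0, 200.0))

    def test_same_seed_is_bit_identical(self, params):
        grid = build_trait_grid(8, params)
        kwargs = dict(nx=16, length=100.0, noise_amplitude=1e-3, seed=42)
        a = make_initial("uniform_community", grid, params, **kwargs)
        b = make_initial("uniform_community", grid, params, **kwargs)
        assert np.array_equal(a.B, b.B)
        c = make_initial("uniform_community", grid, params, nx=16, length=100.0,
                         noise_amplitude=1e-3, seed=43)
        assert not np.array_equal(a.B, c.B)

    def test_hybrid_with_zero_fraction_is_uniform_community(self, params):
        grid = build_trait_grid(8, params)
        kwargs = dict(nx=16, length=100.0, noise_amplitude=1e-4, seed=0)
        hybrid = make_initial("hybrid", grid, params, patterned_fraction=0.0, **kwargs)
        uniform = make_initial("uniform_community", grid, params, **kwargs)
        assert np.array_equal(hybrid.B, uniform.B)

    def test_unknown_kind_rejected(self, params):
        grid = build_trait_grid(8, params)
        with pytest.raises(ValueError):
            make_initial("plasma", grid, params, nx=16, length=100.0)
        with pytest.raises(ValueError):
            make_initial("hybrid", grid, params, nx=16, length=100.0,
                         patterned_fraction=1.5)

    def test_composite_respects_fraction(self, params):
        grid = build_trait_grid(4, params)
        nx = 20
        a = CommunityState(B=np.ones((4, nx)), W=np.ones(nx), H=np.ones(nx), dx=2.0)
        b = CommunityState(B=2 * np.ones((4, nx)), W=np.ones(nx), H=np.ones(nx), dx=2.0)
        comp = composite_state(a, b, 0.25)
        assert (comp.B[:, :5] == 2.0).all()
        assert (comp.B[:, 5:] == 1.0).all()


class TestPatternWavelength:
    def test_uniform_state_has_none(self):
        state = CommunityState(B=np.full((2, 64), 0.05), W=np.ones(64),
                               H=np.ones(64), dx=5.0)
        assert pattern_wavelength(state) is None

    def test_single_mode_signal(self):
        x = np.arange(64) * (324.0 / 64)
        B = 1.0 + 0.1 * np.cos(2 * np.pi * x / 81.0)
        state = CommunityState(B=B[None, :] / 2 * np.ones((2, 1)), W=np.ones(64),
                               H=np.ones(64), dx=324.0 / 64)
        assert pattern_wavelength(state) == pytest.approx(81.0)

    def test_dominant_of_two_modes(self):
        x = np.arange(60) * (600.0 / 60)
        B = 1 + 0.3 * np.cos(2 * np.pi * x / 150.0) + 0.1 * np.cos(2 * np.pi * x / 75.0)
        state = CommunityState(B=B[None, :] * np.ones((2, 1)), W=np.ones(60),
                               H=np.ones(60), dx=10.0)
        assert pattern_wavelength(state) == pytest.approx(150.0)


class TestIntegrate:
    def test_uniform_state_stays_uniform(self):
        # above the Turing threshold a noiseless uniform state is
        # invariant under the periodic spatial operators
        p = ModelParams(P=150.0, D_chi=0.0)
        sg = single_group_grid(1.0, p)
        state = make_initial("single_group", sg, p, nx=32, length=150.0)
        res = integrate(state, sg, p, t_end=500.0, n_chunks=5)
        final = res.final
        assert np.ptp(final.B) < 1e-10 * final.B.max()
        assert np.ptp(final.W) < 1e-10 * final.W.max()

    def test_bare_soil_is_stationary(self):
        p = ModelParams(P=80.0, N=4)
        grid = build_trait_grid(4, p)
        state = make_initial("bare_soil", grid, p, nx=16, length=120.0)
        res = integrate(state, grid, p, t_end=100.0, n_chunks=4)
        assert res.converged
        assert res.final.W == pytest.approx(np.full(16, 20.0), rel=1e-9)
        assert res.final.H == pytest.approx(np.full(16, 200.0), rel=1e-9)

    def test_translation_symmetry(self):
        # translating the initial state translates the final state
        p = ModelParams(P=88.0, D_chi=0.0)
        sg = single_group_grid(1.0, p)
        state = make_initial("single_group", sg, p, nx=48, length=151.4,
                             noise_amplitude=1e-3, seed=9)
        shift = 7
        rolled = CommunityState(B=np.roll(state.B, shift, axis=1),
                                W=np.roll(state.W, shift), H=np.roll(state.H, shift),
                                dx=state.dx)
        res_a = integrate(state, sg, p, t_end=4000.0, steady_tol=1e-9)
        res_b = integrate(rolled, sg, p, t_end=4000.0, steady_tol=1e-9)
        assert np.allclose(
            np.roll(res_a.final.B, shift, axis=1), res_b.final.B,
            rtol=1e-3, atol=1e-8 * res_a.final.B.max(),
        )

    def test_grid_refinement_changes_little(self):
        # halving dx changes the asymptotic norm by < 1% and the
        # wavelength by less than one coarse grid cell
        p = ModelParams(P=85.0, D_chi=0.0)
        sg = single_group_grid(1.0, p)
        results = {}
        for nx in (48, 96):
            state = make_initial("single_group", sg, p, nx=nx, length=151.4)
            x = np.arange(nx) * state.dx
            state.B *= 1.0 + 0.01 * np.cos(2 * np.pi * 2 * x / 151.4)[None, :]
            res = integrate(state, sg, p, t_end=5000.0, steady_tol=1e-9)
            Bbar = res.final.total_biomass
            results[nx] = (np.sqrt(np.mean(Bbar**2)), pattern_wavelength(res.final))
        norm_c, wl_c = results[48]
        norm_f, wl_f = results[96]
        assert norm_f == pytest.approx(norm_c, rel=0.01)
        assert abs(wl_f - wl_c) < 151.4 / 48

    def test_steady_states_are_stationary(self):
        from dryveg.model import rhs

        p = ModelParams(P=85.0, D_chi=0.0)
        sg = single_group_grid(1.0, p)
        state = make_initial("single_group", sg, p, nx=48, length=151.4,
                             noise_amplitude=1e-3, seed=0)
        res = integrate(state, sg, p, t_end=1e5, steady_tol=1e-7)
        assert res.converged
        dB, dW, dH = rhs(res.final, sg, p)
        # residual dominated by the neutral translation mode, which
        # decays only algebraically; the state is stationary to the
        # stepping tolerance
        assert np.abs(dB).max() < 1e-6 * res.final.B.max()

    def test_nonlinear_overland_flow_not_supported_implicitly(self, params):
        sg = single_group_grid(1.0, params)
        state = make_initial("single_group", sg, params, nx=16, length=100.0)
        with pytest.raises(NotImplementedError):
            integrate(state, sg, params.replace(alpha=1.0), t_end=1.0)


class TestSettle:
    def test_agrees_with_trajectory_integrator(self):
        # the steady-state finder must land on the same attractor and
        # the same field values as accurate time integration
        p = ModelParams(P=85.0, D_chi=0.0)
        sg = single_group_grid(1.0, p)
        state = make_initial("single_group", sg, p, nx=48, length=151.4,
                             noise_amplitude=1e-3, seed=4)
        res_bdf = integrate(state, sg, p, t_end=2e4, steady_tol=1e-9)
        res_ptc = settle(state, sg, p)
        assert res_ptc.converged
        from dryveg.spatial import pattern_wavelength

        assert pattern_wavelength(res_ptc.final) == pattern_wavelength(res_bdf.final)
        # same stationary pattern up to a (sub-grid) translation
        a, b = res_bdf.final.total_biomass, res_ptc.final.total_biomass
        assert np.sqrt(np.mean(b**2)) == pytest.approx(
            np.sqrt(np.mean(a**2)), rel=1e-4
        )
        shifts = [np.abs(np.roll(a, s) - b).max() for s in range(48)]
        assert min(shifts) < 0.01 * a.max()
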