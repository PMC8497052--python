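"""Linear analysis of the single-functional-group model."""

import numpy as np
import pytest

from dryveg import ModelParams
from dryveg.spatial import (
    integrate,
    make_initial,
    pattern_wavelength,
    single_group_grid,
)
from dryveg.stability import (
    NoEquilibriumError,
    bare_soil_threshold,
    dispersion_relation,
    trace_branch,
    turing_point,
    uniform_steady_states,
)


class TestBareSoilThreshold:
    @pytest.mark.parametrize("chi, expected", [(1.0, 62.5), (0.0, 112.5)])
    def test_closed_form(self, params, chi, expected):
        assert bare_soil_threshold(chi, params) == pytest.approx(expected)

    def test_decreasing_in_chi(self, params):
        thresholds = [bare_soil_threshold(c, params) for c in np.linspace(0, 1, 9)]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    @pytest.mark.parametrize("chi", [1.0, 0.4])
    def test_agrees_with_seed_fate_in_simulation(self, chi):
        # independent check: a 1e-6 biomass seed on bare soil decays
        # just below P_B and grows just above it
        PB = bare_soil_threshold(chi, ModelParams())
        fates = {}
        for P in (PB - 0.5, PB + 0.5):
            p = ModelParams(P=P, D_chi=0.0)
            sg = single_group_grid(chi, p)
            state = make_initial("bare_soil", sg, p, nx=8, length=100.0)
            state.B[:] = 1e-6
            res = integrate(state, sg, p, t_end=3000.0, steady_tol=1e-12,
                            atol=1e-16, n_chunks=10)
            fates[P] = res.final.B.max()
        assert fates[PB - 0.5] < 1e-7
        assert fates[PB + 0.5] > 1e-5


class TestUniformSteadyStates:
    def test_bare_soil_always_present(self, params):
        for P in (30.0, 100.0, 250.0):
            states = uniform_steady_states(P, 1.0, params)
            B, W, H = states[0]
            assert B == 0.0
            assert W == pytest.approx(P / 4.0)
            assert H == pytest.approx(P / 0.4)

    def test_vegetated_root_satisfies_balance_equations(self, params):
        # brute-force residual check of the returned equilibrium
        states = uniform_steady_states(200.0, 1.0, params)
        B, W, H = states[-1]
        assert B > 0
        lam = 0.032 * 0.1 / (B + 0.1)
        infil = 40.0 * (0.5 * B + 0.01 * 0.06) / (0.5 * B + 0.06)
        evap = 4.0 / (1.0 + 10.0 * B)
        assert abs(lam * W - 0.5) < 1e-10                      # biomass balance
        assert abs(infil * H - evap * W - 20.0 * W * B) < 1e-8  # soil water
        assert abs(200.0 - infil * H) < 1e-8                    # surface water

    def test_small_vegetated_root_appears_above_PB(self, params):
        PB = bare_soil_threshold(1.0, params)
        roots = [s[0] for s in uniform_steady_states(PB + 1.0, 1.0, params) if s[0] > 0]
        assert roots and min(roots) < 0.02

    def test_invalid_precipitation(self, params):
        with pytest.raises(ValueError):
            uniform_steady_states(-5.0, 1.0, params)


class TestDispersionRelation:
    def test_k_zero_matches_numerical_reaction_jacobian(self, params):
        # oracle: finite-difference Jacobian of the local dynamics
        P, chi = 150.0, 1.0
        states = uniform_steady_states(P, chi, params)
        B0, W0, H0 = states[-1]
        p = params.replace(P=P)

        def f(v):
            B, W, H = v
            lam = 0.032 * 0.1 / (B + 0.1)
            infil = 40.0 * (0.5 * B + 0.0006) / (0.5 * B + 0.06)
            evap = 4.0 / (1.0 + 10.0 * B)
            return np.array(
                [lam * W * B - 0.5 * B,
                 infil * H - evap * W - 20.0 * W * B,
                 P - infil * H]
            )

        J = np.empty((3, 3))
        v0 = np.array([B0, W0, H0])
        for j in range(3):
            e = np.zeros(3)
            e[j] = 1e-7 * max(1.0, abs(v0[j]))
            J[:, j] = (f(v0 + e) - f(v0 - e)) / (2 * e[j])
        sigma0 = np.max(np.linalg.eigvals(J).real)

        disp = dispersion_relation(P, chi, params)
        assert disp.sigma_max[0] == pytest.approx(sigma0, abs=1e-6)

    def test_diffusion_dominates_at_large_wavenumber(self, params):
        k = np.array([0.0, 0.1, 1.0, 10.0])
        disp = dispersion_relation(150.0, 1.0, params, k_grid=k, refine=False)
        assert disp.sigma_max[-1] < -100.0
        assert np.all(np.diff(disp.sigma_max[1:]) < 0)

    def test_no_vegetated_state_signalled(self, params):
        with pytest.raises(NoEquilibriumError):
            dispersion_relation(40.0, 1.0, params)


class TestTuringPoint:
    def test_threshold_ordering_and_wavelength(self, params):
        PT1, kc1, wl1 = turing_point(1.0, params)
        PT0, _, _ = turing_point(0.0, params)
        # growth-investing species pattern at higher precipitation
        assert PT0 > PT1
        # patterns form at 80 mm/y but not at 100 (community experiments)
        assert 80.0 < PT1 < 100.0
        assert kc1 > 0
        assert 70.0 < wl1 < 85.0

    def test_threshold_is_a_zero_of_the_growth_rate(self, params):
        PT, _, _ = turing_point(1.0, params)
        assert abs(dispersion_relation(PT, 1.0, params).sigma_c) < 1e-6
        assert dispersion_relation(PT - 2.0, 1.0, params).sigma_c > 0
        assert dispersion_relation(PT + 2.0, 1.0, params).sigma_c < 0

    def test_bad_bracket_signalled(self, params):
        with pytest.raises(ValueError):
            turing_point(1.0, params, P_bracket=(200.0, 300.0))

    def test_simulated_pattern_matches_critical_wavelength(self, params):
        # nonlinear check: on a long domain the emergent pattern picks
        # the admissible mode nearest 2*pi/kc
        PT, kc, wl = turing_point(1.0, params)
        p = ModelParams(P=PT - 1.5, D_chi=0.0)
        sg = single_group_grid(1.0, p)
        length, nx = 1000.0, 250
        state = make_initial("single_group", sg, p, nx=nx, length=length,
                             noise_amplitude=1e-5, seed=5)
        res = integrate(state, sg, p, t_end=5e4, steady_tol=1e-8, n_chunks=20)
        measured = pattern_wavelength(res.final)
        admissible = length / np.arange(1, nx // 2)
        nearest = admissible[np.argmin(np.abs(admissible - wl))]
        assert measured == pytest.approx(nearest, abs=length / nx)

    def test_onset_of_patterning_in_simulation_brackets_threshold(self, params):
        # perturbations of uniform vegetation decay just above P_T and
        # grow into a pattern just below it (threshold check < 2 mm/y)
        PT, _, wl = turing_point(1.0, params)
        outcomes = {}
        for P in (PT - 1.0, PT + 1.0):
            p = ModelParams(P=P, D_chi=0.0)
            sg = single_group_grid(1.0, p)
            state = make_initial("single_group", sg, p, nx=48, length=2 * wl,
                                 noise_amplitude=1e-4, seed=2)
            res = integrate(state, sg, p, t_end=2e4, steady_tol=1e-9, n_chunks=15)
            outcomes[P] = pattern_wavelength(res.final)
        assert outcomes[PT + 1.0] is None
        assert outcomes[PT - 1.0] == pytest.approx(wl, abs=2 * wl / 48)


class TestTraceBranch:
    def test_sweep_down_through_the_turing_bifurcation(self, params):
        PT, _, wl = turing_point(1.0, params)
        sweep = [PT + 8.0, PT + 4.0, PT + 1.0, PT - 2.0, PT - 6.0, PT - 10.0]
        points = trace_branch(1.0, params, sweep, domain_wavelengths=2, seed=1)
        assert len(points) == len(sweep)
        uniform = [pt for pt in points if pt.P > PT]
        patterned = [pt for pt in points if pt.P < PT]
        # uniform branch: norm decreases continuously with P
        norms = [pt.norm for pt in uniform]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert all(pt.wavelength is None for pt in uniform)
        # below threshold the pattern appears and persists
        assert all(pt.wavelength is not None for pt in patterned[1:])

    def test_long_wavelength_pattern_coexists(self, params):
        # subcriticality: at suitable P a pattern of ~2x the Turing
        # wavelength is stable alongside the Turing-wavelength pattern
        from dryveg.model import CommunityState
        from dryveg.steady import settle
        from dryveg.stability import uniform_steady_states

        PT, _, wl = turing_point(1.0, params)
        P = 50.0
        p = ModelParams(P=P, D_chi=0.0)
        sg = single_group_grid(1.0, p)
        nx, length = 64, 2 * wl
        Bv = uniform_steady_states(95.0, 1.0, p)[-1][0]
        x = np.arange(nx) * length / nx
        wls = {}
        for n_per in (1, 2):
            B = Bv * (1 + np.cos(2 * np.pi * n_per * x / length))[None, :]
            state = CommunityState(B=B, W=np.full(nx, 20.0), H=np.full(nx, 5.0),
                                   dx=length / nx)
            res = settle(state, sg, p)
            wls[n_per] = pattern_wavelength(res.final)
        assert wls[2] == pytest.approx(wl, rel=0.02)
        assert wls[1] == pytest.approx(2 * wl, rel=0.02)
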