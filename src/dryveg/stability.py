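"""Linear analysis of the single-functional-group model.

Setting every biomass variable to zero except one reduces the
community model to three fields (B, W, H).  This module locates its
uniform steady states, the bare-soil stability threshold ``P_B``, the
dispersion relation of the vegetated state and the Turing threshold
``P_T`` with its critical wavelength, and traces bifurcation-diagram
branches by hysteresis-aware time-integration sweeps.

The vegetated uniform equilibrium satisfies, with ``Lambda(B) =
lambda0*K/(B+K)``, ``L(B) = L0/(1+R*B)`` and ``I(YB)`` the infiltration
rate:

    Lambda(B) * W = M            (biomass balance)
    H = P / I(YB)                (surface-water balance)
    P = W * (L(B) + Gamma * B)   (soil-water balance, using I*H = P)

which collapses to a single scalar equation for B.  Linearising about
bare soil gives the closed-form threshold ``P_B = M * L0 / lambda0``:
below it a vanishing biomass seed decays, above it grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model import ModelParams

__all__ = [
    "SingleGroupTraits",
    "DispersionResult",
    "BranchPoint",
    "NoEquilibriumError",
    "single_group_traits",
    "uniform_steady_states",
    "bare_soil_threshold",
    "dispersion_relation",
    "turing_point",
    "trace_branch",
]


class NoEquilibriumError(RuntimeError):
    """Raised when a vegetated uniform equilibrium is required but absent."""


@dataclass(frozen=True)
class SingleGroupTraits:
    """Traits K, M, Y of the functional group at trait value chi."""

    chi: float
    K: float
    M: float
    Y: float


def single_group_traits(chi: float, params: ModelParams) -> SingleGroupTraits:
    """Tradeoff-derived traits of a single functional group."""
    if not 0.0 <= chi <= 1.0:
        raise ValueError("chi must lie in [0, 1]")
    return SingleGroupTraits(
        chi=chi,
        K=params.K_max + chi * (params.K_min - params.K_max),
        M=params.M_max + chi * (params.M_min - params.M_max),
        Y=params.Y_max + chi * (params.Y_min - params.Y_max),
    )


@dataclass
class DispersionResult:
    """Linear growth rates of spatial modes about a uniform state."""

    k: np.ndarray           # wavenumbers [1/m]
    sigma_max: np.ndarray   # largest real part of the 3x3 eigenvalues [1/y]
    kc: float               # wavenumber of the fastest-growing mode [1/m]
    sigma_c: float          # growth rate at kc [1/y]
    P: float                # precipitation the relation was evaluated at [mm/y]
    chi: float

    @property
    def wavelength(self) -> float:
        """Wavelength 2*pi/kc of the fastest-growing mode [m]."""
        return 2.0 * np.pi / self.kc if self.kc > 0 else np.inf


@dataclass(frozen=True)
class BranchPoint:
    """One point of a bifurcation-diagram branch."""

    P: float
    norm: float                  # sqrt(mean over x of B^2), domain-size free
    wavelength: float | None     # None for uniform states
    stable: bool


def bare_soil_threshold(chi: float, params: ModelParams) -> float:
    """Precipitation P_B below which bare soil is linearly stable [mm/y].

    Closed form M(chi) * L0 / lambda0, from the growth rate
    ``lambda0 * P / L0 - M`` of an infinitesimal biomass seed on bare
    soil (where W = P/L0).
    """
    tr = single_group_traits(chi, params)
    return tr.M * params.L0 / params.lambda0


def _vegetated_residual(B: float, tr: SingleGroupTraits, params: ModelParams) -> float:
    """Scalar equilibrium condition g(B) = W*(B)*(L(B) + Gamma*B) - P."""
    W = tr.M * (B + tr.K) / (params.lambda0 * tr.K)
    L = params.L0 / (1.0 + params.R * B)
    return W * (L + params.gamma * B) - params.P


def uniform_steady_states(
    P: float, chi: float, params: ModelParams, B_max: float = 50.0, n_scan: int = 2000
) -> list[tuple[float, float, float]]:
    """All uniform equilibria (B, W, H) of the single-group model at (P, chi).

    The bare-soil state (0, P/L0, P/(f A)) always exists; vegetated
    roots are found by bracketing sign changes of the scalar residual
    on a fine biomass scan and polishing with Brent's method.  Returned
    sorted by increasing B.
    """
    if P <= 0:
        raise ValueError("precipitation must be positive")
    p = params.replace(P=float(P))
    tr = single_group_traits(chi, p)
    states = [(0.0, P / p.L0, P / (p.f * p.A))]
    Bs = np.linspace(1e-8, B_max, n_scan)
    g = np.array([_vegetated_residual(b, tr, p) for b in Bs])
    sign_flip = np.flatnonzero(np.sign(g[:-1]) != np.sign(g[1:]))
    for j in sign_flip:
        B = brentq(_vegetated_residual, Bs[j], Bs[j + 1], args=(tr, p), xtol=1e-12)
        if B <= 1e-7:
            continue
        W = tr.M * (B + tr.K) / (p.lambda0 * tr.K)
        infil = p.A * (tr.Y * B + p.f * p.Q) / (tr.Y * B + p.Q)
        H = P / infil
        states.append((B, W, H))
    states.sort(key=lambda s: s[0])
    return states


def _reaction_jacobian(
    B: float, W: float, H: float, tr: SingleGroupTraits, params: ModelParams
) -> np.ndarray:
    """3x3 Jacobian of the local (reaction) dynamics about (B, W, H)."""
    lam = params.lambda0 * tr.K / (B + tr.K)
    dlam = -lam / (B + tr.K)
    Bbb = tr.Y * B
    infil = params.A * (Bbb + params.f * params.Q) / (Bbb + params.Q)
    dinfil = params.A * params.Q * (1.0 - params.f) / (Bbb + params.Q) ** 2 * tr.Y
    evap = params.L0 / (1.0 + params.R * B)
    devap = -params.L0 * params.R / (1.0 + params.R * B) ** 2
    return np.array(
        [
            [W * (lam + B * dlam) - tr.M, lam * B, 0.0],
            [dinfil * H - devap * W - params.gamma * W, -evap - params.gamma * B, infil],
            [-dinfil * H, 0.0, -infil],
        ]
    )


def _vegetated_state(P: float, chi: float, params: ModelParams):
    states = uniform_steady_states(P, chi, params)
    vegetated = [s for s in states if s[0] > 0]
    if not vegetated:
        raise NoEquilibriumError(
            f"no vegetated uniform state at P = {P:g} mm/y, chi = {chi:g}"
        )
    return vegetated[-1]  # upper (largest-B) branch


def dispersion_relation(
    P: float,
    chi: float,
    params: ModelParams,
    k_grid: np.ndarray | None = None,
    refine: bool = True,
) -> DispersionResult:
    """Growth rate of spatial perturbations about the vegetated uniform state.

    For each wavenumber k the 3x3 linearisation is the reaction
    Jacobian minus ``k^2 * diag(D_B, D_W, D_H)``; the relation reports
    the largest eigenvalue real part.  At k = 0 it reduces to the
    reaction Jacobian itself; for large k diffusion dominates and all
    modes decay.  The maximising wavenumber is refined by a bounded
    scalar optimisation between its grid neighbours.
    """
    p = params.replace(P=float(P))
    tr = single_group_traits(chi, p)
    B, W, H = _vegetated_state(P, chi, p)
    J0 = _reaction_jacobian(B, W, H, tr, p)
    D = np.array([p.D_B, p.D_W, p.D_H])

    if k_grid is None:
        # wavelengths 5 m .. 500 m, log-spaced, plus the homogeneous mode
        k_grid = np.concatenate([[0.0], 2.0 * np.pi / np.geomspace(500.0, 5.0, 200)])
    k_grid = np.asarray(k_grid, dtype=float)

    def sigma(k: float) -> float:
        return float(np.max(np.linalg.eigvals(J0 - k**2 * np.diag(D)).real))

    sig = np.array([sigma(k) for k in k_grid])
    positive = k_grid > 0
    j = int(np.argmax(np.where(positive, sig, -np.inf)))
    kc, sc = k_grid[j], sig[j]
    if refine and 0 < j < len(k_grid) - 1:
        res = minimize_scalar(
            lambda k: -sigma(k),
            bounds=(k_grid[j - 1], k_grid[j + 1]),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if res.success and -res.fun >= sc:
            kc, sc = float(res.x), float(-res.fun)
    return DispersionResult(k=k_grid, sigma_max=sig, kc=kc, sigma_c=sc, P=float(P), chi=chi)


def turing_point(
    chi: float,
    params: ModelParams,
    P_bracket: tuple[float, float] | None = None,
    tol: float = 1e-8,
) -> tuple[float, float, float]:
    """Turing threshold of uniform vegetation: (P_T, kc, wavelength).

    Bisects precipitation inside ``P_bracket`` for the zero crossing of
    the maximal finite-wavelength growth rate; uniform vegetation is
    Turing-unstable for P below the returned threshold.  The default
    bracket spans from just above the bare-soil threshold (below which
    no vegetated state needs to exist) to 400 mm/y.
    """
    if P_bracket is None:
        P_bracket = (bare_soil_threshold(chi, params) + 0.5, 400.0)

    def max_sigma(P: float) -> float:
        return dispersion_relation(P, chi, params).sigma_c

    lo, hi = P_bracket
    s_lo, s_hi = max_sigma(lo), max_sigma(hi)
    if s_lo * s_hi > 0:
        raise ValueError(
            f"no Turing sign change in P bracket {P_bracket}: "
            f"sigma({lo}) = {s_lo:.3g}, sigma({hi}) = {s_hi:.3g}"
        )
    while hi - lo > 1e-10 * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        s_mid = max_sigma(mid)
        if abs(s_mid) < tol:
            lo = hi = mid
            break
        if s_mid * s_lo > 0:
            lo, s_lo = mid, s_mid
        else:
            hi = mid
    PT = 0.5 * (lo + hi)
    disp = dispersion_relation(PT, chi, params)
    return PT, disp.kc, disp.wavelength


def trace_branch(
    chi: float,
    params: ModelParams,
    P_sweep,
    domain_wavelengths: int = 2,
    noise_amplitude: float = 1e-4,
    seed: int = 0,
    t_end: float = 2000.0,
    steady_tol: float = 1e-7,
    points_per_wavelength: int = 24,
) -> list[BranchPoint]:
    """Trace a bifurcation branch by sweeping P with time integration.

    Starting from the vegetated uniform state (plus a small seeded
    biomass perturbation) at the first precipitation of the sweep, each
    subsequent P is integrated from the previous asymptotic state --
    the hysteresis-aware protocol a sweep experiment realises.  Records
    the biomass L2 norm ``sqrt(mean_x B^2)``, the detected wavelength
    and whether the state persisted.  Only stable branches are
    reachable this way; wavelength changes are recorded as branch-end
    events in the returned sequence, not errors.
    """
    from .spatial import integrate, make_initial, pattern_wavelength, single_group_grid

    P_sweep = list(P_sweep)
    PT, kc, wl = turing_point(chi, params)
    length = domain_wavelengths * wl
    nx = domain_wavelengths * points_per_wavelength

    p0 = params.replace(P=float(P_sweep[0]), D_chi=0.0)
    sg = single_group_grid(chi, p0)
    state = make_initial(
        "single_group",
        sg,
        p0,
        nx=nx,
        length=length,
        chi=chi,
        noise_amplitude=noise_amplitude,
        seed=seed,
    )
    points: list[BranchPoint] = []
    for P in P_sweep:
        p = p0.replace(P=float(P))
        try:
            result = integrate(state, sg, p, t_end=t_end,
                               steady_tol=steady_tol)
            state = result.final
            norm = float(np.sqrt(np.mean(state.total_biomass**2)))
            wl_here = pattern_wavelength(state)
            points.append(
                BranchPoint(P=float(P), norm=norm, wavelength=wl_here,
                            stable=bool(result.converged))
            )
        except Exception:
            points.append(BranchPoint(P=float(P), norm=np.nan, wavelength=None,
                                      stable=False))
            break
    return points
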