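"""Core trait-structured community model of dryland vegetation.

The model couples ``N`` plant functional groups, distinguished by a
dimensionless tradeoff trait ``chi`` in (0, 1], to two water
compartments on a one-dimensional periodic domain:

* ``B_i(x)`` -- above-ground biomass of functional group ``i`` [kg/m^2],
* ``W(x)``   -- soil (below-ground) water content [kg/m^2],
* ``H(x)``   -- surface (overland) water height [kg/m^2].

The trait interpolates a growth/tolerance tradeoff: ``chi -> 0`` plants
invest in shoot growth (high light-capture capacity ``K``, high
mortality ``M``, strong infiltration contribution ``Y``), ``chi -> 1``
plants invest in tolerating water stress (low ``K``, ``M``, ``Y``).
Biomass grows at a light-limited rate ``Lambda_i(Bbar) * W``, dies at
rate ``M_i``, disperses diffusively in space and "diffuses" along the
trait axis at a very small rate ``D_chi`` representing mutations to
neighbouring functional groups.  Surface water infiltrates at a
biomass-enhanced rate, which is the scale-dependent feedback that can
destabilise uniform vegetation into periodic (Turing) patterns.

Everything here is local-in-time: parameter containers, the trait grid
with its tradeoff-derived traits, the local rate functions, and the
full right-hand-side tendency of the coupled PDE system.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "TraitGrid",
    "CommunityState",
    "build_trait_grid",
    "growth_rates",
    "infiltration_rate",
    "evaporation_rate",
    "trait_laplacian",
    "rhs",
    "bare_soil_state",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ModelParams:
    """Model constants with their standard values.

    Units: rates in 1/y or m^2/(kg*y), biomasses and water contents in
    kg/m^2, precipitation ``P`` in mm/y (1 mm of rain = 1 kg/m^2, so
    mm/y and kg/(m^2*y) are used interchangeably), diffusivities in
    m^2/y.
    """

    lambda0: float = 0.032   # growth rate at zero biomass [m^2/(kg*y)]
    gamma: float = 20.0      # water uptake rate [m^2/(kg*y)]
    f: float = 0.01          # infiltration contrast (f << 1: high contrast) [-]
    A: float = 40.0          # maximal infiltration rate [1/y]
    Q: float = 0.06          # reference biomass for infiltration [kg/m^2]
    L0: float = 4.0          # bare-soil evaporation rate [1/y]
    R: float = 10.0          # evaporation reduction by shading [m^2/kg]
    K_min: float = 0.1       # minimal light-capture capacity [kg/m^2]
    K_max: float = 0.6       # maximal light-capture capacity [kg/m^2]
    M_min: float = 0.5       # minimal mortality rate [1/y]
    M_max: float = 0.9       # maximal mortality rate [1/y]
    Y_min: float = 0.5       # minimal infiltration contribution [-]
    Y_max: float = 1.5       # maximal infiltration contribution [-]
    P: float = 150.0         # precipitation rate [mm/y]
    N: int = 128             # number of functional groups [-]
    D_B: float = 1.0         # biomass dispersal [m^2/y]
    D_W: float = 100.0       # soil-water diffusion [m^2/y]
    D_H: float = 1.0e4       # overland-water diffusion [m^2/y]
    D_chi: float = 1.0e-6    # trait diffusion (mutation) rate [1/y]
    alpha: float = 0.0       # overland-flow nonlinearity exponent [-]

    def __post_init__(self) -> None:
        positive = (
            "lambda0", "gamma", "A", "Q", "L0", "R",
            "K_min", "K_max", "M_min", "M_max", "Y_min", "Y_max",
            "P", "D_B", "D_W", "D_H",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if not 0 <= self.f <= 1:
            raise ValueError("infiltration contrast f must lie in [0, 1]")
        if not self.K_min < self.K_max:
            raise ValueError("K_min must be smaller than K_max")
        if not self.M_min < self.M_max:
            raise ValueError("M_min must be smaller than M_max")
        if not self.Y_min < self.Y_max:
            raise ValueError("Y_min must be smaller than Y_max")
        if self.N < 2:
            raise ValueError("at least two functional groups are required")
        if self.D_chi < 0:
            raise ValueError("trait diffusion rate must be non-negative")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ModelParams":
        """Read parameters from a YAML or JSON config file.

        Keys mirror the field names; omitted keys keep their defaults.
        """
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls(**data)


@dataclass(frozen=True)
class TraitGrid:
    """Discretisation of the tradeoff trait into N functional groups.

    Group ``i`` (1-based) covers the trait interval of width
    ``dchi = 1/N`` preceding ``chi_i = i/N``; its traits follow the
    linear tradeoff relations K(chi), M(chi), Y(chi).
    """

    chi: np.ndarray  # trait values chi_i = i/N, i = 1..N
    K: np.ndarray    # light-capture capacity per group [kg/m^2]
    M: np.ndarray    # mortality rate per group [1/y]
    Y: np.ndarray    # infiltration contribution per group [-]

    @property
    def N(self) -> int:
        return self.chi.size

    @property
    def dchi(self) -> float:
        return 1.0 / self.N


def build_trait_grid(N: int, params: ModelParams) -> TraitGrid:
    """Build the trait grid chi_i = i/N with tradeoff-derived traits.

    The tradeoff relations are linear interpolations between the trait
    extremes: growth-investing plants (chi -> 0) have the largest
    light-capture capacity but also the largest mortality and the
    strongest infiltration contribution.
    """
    if not isinstance(N, (int, np.integer)) or N < 2:
        raise ValueError("N must be an integer >= 2")
    chi = np.arange(1, N + 1, dtype=float) / N
    K = params.K_max + chi * (params.K_min - params.K_max)
    M = params.M_max + chi * (params.M_min - params.M_max)
    Y = params.Y_max + chi * (params.Y_min - params.Y_max)
    return TraitGrid(chi=chi, K=K, M=M, Y=Y)


@dataclass
class CommunityState:
    """Community fields on a uniform 1-D periodic spatial grid.

    ``B`` holds per-bin biomass (shape ``N x Nx``): the biomass of all
    species in one trait interval, not a density per unit trait length.
    The trait-space density ``b_i = N * B_i`` is a derived view.
    """

    B: np.ndarray   # biomass per group per grid point [kg/m^2], (N, Nx)
    W: np.ndarray   # soil water [kg/m^2], (Nx,)
    H: np.ndarray   # surface water [kg/m^2], (Nx,)
    dx: float       # grid spacing [m]
    t: float = 0.0  # time [y]

    def __post_init__(self) -> None:
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.B.shape[1] != self.W.size or self.W.size != self.H.size:
            raise ValueError("B, W, H have inconsistent spatial shapes")
        if self.W.size < 4:
            raise ValueError("need at least 4 spatial grid points")

    @property
    def nx(self) -> int:
        return self.W.size

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    @property
    def length(self) -> float:
        return self.nx * self.dx

    @property
    def total_biomass(self) -> np.ndarray:
        """Bbar(x) = sum over groups of B_i(x)."""
        return self.B.sum(axis=0)

    @property
    def trait_density(self) -> np.ndarray:
        """Biomass density per unit trait length, b_i = N * B_i."""
        return self.B * self.B.shape[0]

    def mean_distribution(self) -> np.ndarray:
        """Space-averaged biomass per functional group."""
        return self.B.mean(axis=1)

    def copy(self) -> "CommunityState":
        return CommunityState(
            B=self.B.copy(), W=self.W.copy(), H=self.H.copy(), dx=self.dx, t=self.t
        )


def _check_nonnegative(value: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def growth_rates(B_total: ArrayLike, grid: TraitGrid, params: ModelParams) -> np.ndarray:
    """Light-limited growth rate Lambda_i = lambda0 * K_i / (Bbar + K_i).

    Shading by the total standing biomass Bbar attenuates growth; the
    capacity K_i sets how tolerant group ``i`` is to that attenuation.
    Broadcasts: scalar Bbar -> (N,), array Bbar of shape (Nx,) -> (N, Nx).
    """
    Bbar = _check_nonnegative(B_total, "total biomass Bbar")
    K = grid.K if np.ndim(Bbar) == 0 else grid.K[:, None]
    return params.lambda0 * K / (Bbar + K)


def infiltration_rate(B_weighted: ArrayLike, params: ModelParams) -> ArrayLike:
    """Infiltration rate I = A (Bbb + f Q) / (Bbb + Q).

    ``Bbb = sum_j Y_j B_j`` is the infiltration-weighted biomass.  The
    rate rises from ``f*A`` over bare soil to ``A`` under dense
    vegetation -- the differential infiltration that routes overland
    water towards vegetated patches.
    """
    Bbb = _check_nonnegative(B_weighted, "weighted biomass Bbb")
    return params.A * (Bbb + params.f * params.Q) / (Bbb + params.Q)


def evaporation_rate(B_total: ArrayLike, params: ModelParams) -> ArrayLike:
    """Evaporation rate L = L0 / (1 + R*Bbar), reduced by canopy shading."""
    Bbar = _check_nonnegative(B_total, "total biomass Bbar")
    return params.L0 / (1.0 + params.R * Bbar)


def trait_laplacian(B: np.ndarray, N: int | None = None) -> np.ndarray:
    """Discrete second derivative along the trait axis, N^2 * (B_{i+1} - 2 B_i + B_{i-1}).

    Models mutations to neighbouring functional groups.  The trait-axis
    boundaries use reflecting ghost bins (B_0 = B_1, B_{N+1} = B_N), a
    zero-flux closure that conserves total biomass exactly: the outputs
    sum to zero along the trait axis.

    ``B`` may be (N,) or (N, Nx); the operator acts along axis 0.
    """
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    if N is None:
        N = n
    elif N != n:
        raise ValueError(f"trait axis has {n} bins, expected {N}")
    if n < 2:
        raise ValueError("need at least 2 trait bins")
    out = np.empty_like(B)
    out[1:-1] = B[2:] - 2.0 * B[1:-1] + B[:-2]
    out[0] = B[1] - B[0]      # ghost B_0 = B_1
    out[-1] = B[-2] - B[-1]   # ghost B_{N+1} = B_N
    out *= float(N) ** 2
    return out


def _periodic_laplacian(field: np.ndarray, dx: float, axis: int = -1) -> np.ndarray:
    """Second-order central-difference Laplacian on a periodic axis."""
    return (
        np.roll(field, -1, axis=axis) - 2.0 * field + np.roll(field, 1, axis=axis)
    ) / dx**2


def rhs(
    state: CommunityState, grid: TraitGrid, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full tendency (dB/dt, dW/dt, dH/dt) of the community model.

    dB_i/dt = Lambda_i W B_i - M_i B_i + D_B d^2B_i/dx^2 + D_chi d^2B_i/dchi^2
    dW/dt   = I H - L W - Gamma W Bbar + D_W d^2W/dx^2
    dH/dt   = P - I H + D_H d/dx(H^alpha dH/dx)

    Spatial derivatives are periodic; with the default ``alpha = 0``
    overland flow reduces to linear diffusion.  All rate terms are
    evaluated pointwise in x.
    """
    B, W, H = state.B, state.W, state.H
    for name, field in (("B", B), ("W", W), ("H", H)):
        if not np.all(np.isfinite(field)):
            raise ValueError(f"field {name} contains non-finite values")
        if np.any(field < 0):
            raise ValueError(f"field {name} contains negative values")
    if B.shape[0] != grid.N:
        raise ValueError("state and trait grid disagree on the number of groups")

    Bbar = B.sum(axis=0)
    Bbb = (grid.Y[:, None] * B).sum(axis=0)
    lam = growth_rates(Bbar, grid, params)
    I = infiltration_rate(Bbb, params)
    L = evaporation_rate(Bbar, params)

    dB = (lam * W[None, :] - grid.M[:, None]) * B
    dB += params.D_B * _periodic_laplacian(B, state.dx, axis=1)
    if params.D_chi > 0:
        dB += params.D_chi * trait_laplacian(B)

    dW = I * H - L * W - params.gamma * W * Bbar
    dW += params.D_W * _periodic_laplacian(W, state.dx)

    dH = params.P - I * H
    if params.alpha == 0:
        dH += params.D_H * _periodic_laplacian(H, state.dx)
    else:
        # conservative form d/dx(H^alpha dH/dx) via midpoint fluxes
        Hm = 0.5 * (H + np.roll(H, 1))
        flux = Hm**params.alpha * (H - np.roll(H, 1)) / state.dx
        dH += params.D_H * (np.roll(flux, -1) - flux) / state.dx

    return dB, dW, dH


def bare_soil_state(params: ModelParams) -> tuple[float, float]:
    """Soil/surface water of the bare-soil fixed point: W = P/L0, H = P/(f A)."""
    return params.P / params.L0, params.P / (params.f * params.A)
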