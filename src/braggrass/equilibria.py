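"""Spatially uniform equilibria of the coupled wave-seagrass model.

The uniform seagrass density n0 obeys the steady, space-independent limit
of the seagrass equation

    0 = -(omega_b + omega_c * tau_b0) * n0 + alpha * n0^2 - beta * n0^3,

where the uniform bed shear stress tau_b0 itself depends on n0 through the
meadow-built topography: the matte reduces the water depth, H0 = h - s*n0,
which shortens the forcing wave (dispersion) and strengthens the near-bed
orbital velocity. The self-consistent vegetated state is found by damped
fixed-point iteration; the bare state (n0 = 0) is closed-form.

The transcritical point a* is the forcing amplitude at which the net
mortality of the bare state vanishes, omega(a*, n0=0) = 0:

    a* = sinh(kappa_h h)/sigma * sqrt(-2 omega_b / (rho f_w omega_c)).

Biological rates (omega_b, omega_c, alpha, beta, delta) are expressed per
*biological time unit*; only their ratios and the products with tau_b [Pa]
matter for equilibria and thresholds, so the unit choice is free here (the
simulator fixes it via its bio_timescale parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .linear_wave_core import WaveParameters, solve_dispersion

__all__ = [
    "SeagrassParams",
    "BasicState",
    "default_wave_parameters",
    "default_seagrass_params",
    "uniform_equilibrium",
    "critical_amplitude",
    "omega_c_for_critical_amplitude",
    "homogeneous_stability",
    "bifurcation_diagram",
]


@dataclass(frozen=True)
class SeagrassParams:
    """Seagrass growth/mortality parameters and the topography coupling.

    Rates are per biological time unit; ``omega_c`` converts bed shear
    stress [Pa] to a mortality rate; ``s`` converts seagrass density to
    matte height [m]; ``h`` is the bare-bed water depth [m].
    """

    omega_b: float  #: background net mortality (< 0: net growth without waves)
    omega_c: float  #: stress-mortality coupling [1/(bio unit * Pa)]
    alpha: float  #: facilitation coefficient
    beta: float  #: competition coefficient (> 0)
    delta: float  #: lateral dispersion [m^2 / bio unit]
    s: float  #: topography coefficient [m per unit density]
    h: float  #: bare-bed depth [m]

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.delta < 0 or self.s < 0:
            raise ValueError("delta and s must be >= 0")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if self.omega_b >= 0:
            raise ValueError(
                "omega_b must be < 0 (net growth in absence of waves), "
                f"got {self.omega_b}"
            )


@dataclass(frozen=True)
class BasicState:
    """Uniform equilibrium at forcing amplitude a."""

    a: float
    n0: float
    H0: float
    kappa: float
    tau_b0: float  #: uniform time-averaged bed shear stress [Pa]
    omega0: float  #: net mortality omega_b + omega_c * tau_b0
    branch: str  #: "vegetated" or "bare"
    exists: bool = True  #: False when no nonnegative vegetated root exists


# --- documented default parameter set -------------------------------------
#
# T = 8 s waves over a shallow bare-bed depth h = 4 m, the depth range in
# which banded seagrass patterns are surveyed in the field (bare-bed
# wavelength ~ 47 m). Biology in scaled units with omega_b = -1, alpha = 0,
# beta = 2, so the unforced meadow density is n0(a=0) = sqrt(1/2); the
# topography coefficient s = sqrt(2) then gives a 1 m matte at full
# density. omega_c = 0.0759 places the transcritical point at a* = 0.5 m.
# delta = 0.1 m^2 per biological unit weakly damps short-wave structure.
# The default forcing amplitude a = 0.475 m (0.95 a*) sits in the upper
# part of the modulation-instability window, where pattern growth is
# strongest and wavenumber selection sharpest.

DEFAULT_T = 8.0
DEFAULT_H_BARE = 4.0


def default_wave_parameters(a: float = 0.475, T: float = DEFAULT_T) -> WaveParameters:
    return WaveParameters(a=a, T=T)


def default_seagrass_params() -> SeagrassParams:
    return SeagrassParams(
        omega_b=-1.0,
        omega_c=0.07593300449482696,  # places a* at 0.50 m for the defaults above
        alpha=0.0,
        beta=2.0,
        delta=0.1,
        s=math.sqrt(2.0),
        h=DEFAULT_H_BARE,
    )


def _tau_b0(a: float, sigma: float, kappa: float, H: float,
            rho: float, f_w: float) -> float:
    """Uniform wave-averaged bed shear stress of the basic wave field."""
    U_b0 = sigma * a / math.sinh(kappa * H)
    return 0.5 * rho * f_w * U_b0 * U_b0


def _largest_root(omega0: float, alpha: float, beta: float) -> float | None:
    """Largest nonnegative root of -omega0 + alpha*n - beta*n^2 = 0 (n > 0 factor)."""
    disc = alpha * alpha - 4.0 * beta * omega0
    if disc < 0:
        return None
    root = (alpha + math.sqrt(disc)) / (2.0 * beta)
    return root if root >= 0 else None


def uniform_equilibrium(
    a: float,
    T: float,
    wp: WaveParameters,
    sp: SeagrassParams,
    branch: str = "vegetated",
) -> BasicState:
    """Solve the uniform basic state on the requested branch.

    The bare branch returns n0 = 0 with the shear stress evaluated at the
    bare depth h. The vegetated branch solves the self-consistent system
    {kappa(H0), U_b0, tau_b0, cubic balance} by damped fixed-point
    iteration (damping 0.5) to |d n0| < 1e-10, returning the largest
    nonnegative root. If at convergence no nonnegative root exists the
    state is flagged ``exists=False`` with n0 = 0.
    """
    if a < 0:
        raise ValueError(f"forcing amplitude must be >= 0, got {a}")
    if branch not in ("vegetated", "bare"):
        raise ValueError(f"branch must be 'vegetated' or 'bare', got {branch!r}")
    sigma = 2.0 * math.pi / T
    rho, f_w = wp.rho, wp.f_w

    if branch == "bare":
        ds = solve_dispersion(T, sp.h, g=wp.g)
        tau = _tau_b0(a, sigma, ds.kappa, sp.h, rho, f_w)
        return BasicState(a=a, n0=0.0, H0=sp.h, kappa=ds.kappa, tau_b0=tau,
                          omega0=sp.omega_b + sp.omega_c * tau, branch="bare")

    n0 = _largest_root(sp.omega_b, sp.alpha, sp.beta) or 0.0  # a=0 guess
    if sp.s == 0.0:
        # no topographic feedback: the root is direct, no iteration needed
        kappa = solve_dispersion(T, sp.h, g=wp.g).kappa
        tau = _tau_b0(a, sigma, kappa, sp.h, rho, f_w)
        omega0 = sp.omega_b + sp.omega_c * tau
        n0 = _largest_root(omega0, sp.alpha, sp.beta)
        if n0 is None or (n0 < 1e-9 and omega0 > 0):
            return BasicState(a=a, n0=0.0, H0=sp.h, kappa=kappa, tau_b0=tau,
                              omega0=omega0, branch="vegetated", exists=False)
        return BasicState(a=a, n0=n0, H0=sp.h, kappa=kappa, tau_b0=tau,
                          omega0=omega0, branch="vegetated")
    for _ in range(10_000):
        H0 = sp.h - sp.s * n0
        if H0 <= 0:
            raise ValueError(
                f"meadow reaches the surface during iteration (H0={H0:.3g} m); "
                "model validity lost"
            )
        kappa = solve_dispersion(T, H0, g=wp.g).kappa
        tau = _tau_b0(a, sigma, kappa, H0, rho, f_w)
        omega0 = sp.omega_b + sp.omega_c * tau
        # an iterate without a nonnegative root proposes n0 = 0; nonexistence
        # is only declared at convergence (the stress at an overgrown guess
        # can overshoot even when a self-consistent sparse meadow exists)
        root = _largest_root(omega0, sp.alpha, sp.beta) or 0.0
        new = n0 + 0.5 * (root - n0)
        if abs(new - n0) < 5e-14:
            n0 = new
            break
        n0 = new
    else:
        # near the transcritical point the root has square-root behaviour in
        # omega0 and the damped map can cycle; fall back to bracketed
        # root-finding on G(n) = largest_root(omega0(n)) - n (monotone there)
        def _gap(n: float) -> float:
            H = sp.h - sp.s * n
            if H <= 0:
                return -n
            kap = solve_dispersion(T, H, g=wp.g).kappa
            om = sp.omega_b + sp.omega_c * _tau_b0(a, sigma, kap, H, rho, f_w)
            return (_largest_root(om, sp.alpha, sp.beta) or 0.0) - n

        n_hi = min((_largest_root(sp.omega_b, sp.alpha, sp.beta) or 0.0) * 1.5 + 1e-6,
                   0.999 * sp.h / sp.s if sp.s > 0 else float("inf"))
        if _gap(0.0) <= 0:
            n0 = 0.0
        else:
            from scipy.optimize import brentq as _brentq
            n0 = _brentq(_gap, 0.0, n_hi, xtol=1e-14)

    if n0 < 1e-9:
        ds = solve_dispersion(T, sp.h, g=wp.g)
        tau_h = _tau_b0(a, sigma, ds.kappa, sp.h, rho, f_w)
        omega_h = sp.omega_b + sp.omega_c * tau_h
        if omega_h > 0:  # beyond the transcritical point: bare state only
            return BasicState(a=a, n0=0.0, H0=sp.h, kappa=ds.kappa, tau_b0=tau_h,
                              omega0=omega_h, branch="vegetated", exists=False)

    H0 = sp.h - sp.s * n0
    kappa = solve_dispersion(T, H0, g=wp.g).kappa
    tau = _tau_b0(a, sigma, kappa, H0, rho, f_w)
    omega0 = sp.omega_b + sp.omega_c * tau
    return BasicState(a=a, n0=n0, H0=H0, kappa=kappa, tau_b0=tau,
                      omega0=omega0, branch="vegetated")


def critical_amplitude(T: float, wp: WaveParameters, sp: SeagrassParams) -> float:
    """Transcritical amplitude a*: omega(a*, n0=0) = 0, closed form.

    a* = sinh(kappa_h h)/sigma * sqrt(-2 omega_b / (rho f_w omega_c)),
    with kappa_h the wavenumber at the bare depth h.
    """
    if sp.omega_c <= 0:
        raise ValueError("critical amplitude requires omega_c > 0")
    sigma = 2.0 * math.pi / T
    kappa_h = solve_dispersion(T, sp.h, g=wp.g).kappa
    return (math.sinh(kappa_h * sp.h) / sigma) * math.sqrt(
        -2.0 * sp.omega_b / (wp.rho * wp.f_w * sp.omega_c)
    )


def omega_c_for_critical_amplitude(a_star: float, T: float, wp: WaveParameters,
                                   sp: SeagrassParams) -> float:
    """Coupling strength that places the transcritical point at ``a_star``."""
    sigma = 2.0 * math.pi / T
    kappa_h = solve_dispersion(T, sp.h, g=wp.g).kappa
    return -2.0 * sp.omega_b * math.sinh(kappa_h * sp.h) ** 2 / (
        wp.rho * wp.f_w * sigma * sigma * a_star * a_star
    )


def homogeneous_stability(a: float, T: float, wp: WaveParameters,
                          sp: SeagrassParams) -> float:
    """Growth rate of uniform perturbations about the bare state n0 = 0.

    Returns -omega(a, n0=0): positive (bare state invadable by vegetation)
    for a < a*, zero at a*, negative beyond.
    """
    bare = uniform_equilibrium(a, T, wp, sp, branch="bare")
    return -bare.omega0


def bifurcation_diagram(a_grid: np.ndarray, T: float, wp: WaveParameters,
                        sp: SeagrassParams) -> pd.DataFrame:
    """Tabulate both uniform branches over an amplitude grid.

    Columns: a, a_rel (= a/a*), n0_veg, n0_bare, kappa_veg, kappa_bare,
    tau_b0_veg, tau_b0_bare, veg_exists.
    """
    a_star = critical_amplitude(T, wp, sp)
    rows = []
    for a in np.asarray(a_grid, dtype=float):
        veg = uniform_equilibrium(a, T, wp, sp, branch="vegetated")
        bare = uniform_equilibrium(a, T, wp, sp, branch="bare")
        rows.append(
            {"a": a, "a_rel": a / a_star, "n0_veg": veg.n0, "n0_bare": bare.n0,
             "kappa_veg": veg.kappa, "kappa_bare": bare.kappa,
             "tau_b0_veg": veg.tau_b0, "tau_b0_bare": bare.tau_b0,
             "veg_exists": veg.exists}
        )
    df = pd.DataFrame(rows)
    df.attrs["a_star"] = a_star
    return df


def steady_state_residual(state: BasicState, sp: SeagrassParams) -> float:
    """Residual of the uniform steady-state seagrass balance at a state."""
    n0 = state.n0
    return abs(-state.omega0 * n0 + sp.alpha * n0 ** 2 - sp.beta * n0 ** 3)
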