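"""Linear (Airy) wave theory primitives.

Closed-form and root-finding building blocks used throughout the package:
the dispersion relation sigma^2 = g*kappa*tanh(kappa*H), deep-water and
shoaled wavelengths, near-bed orbital kinematics and the wave-averaged bed
shear stress, and the analytic monochromatic basic-state wave fields
(eta0, phi0, u0, w0) over a flat bed.

All quantities are SI: metres, seconds, radians, pascals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GRAVITY",
    "RHO_SEAWATER",
    "FRICTION_FACTOR",
    "WaveParameters",
    "DispersionSolution",
    "BottomKinematics",
    "solve_dispersion",
    "deep_water_wavelength",
    "shoal_wavelength",
    "bottom_kinematics",
    "basic_wave_fields",
]

#: default gravitational acceleration [m/s^2]
GRAVITY = 9.81
#: default seawater density [kg/m^3]
RHO_SEAWATER = 1025.0
#: default (constant) wave friction factor [-]
FRICTION_FACTOR = 0.05

_DISPERSION_RTOL = 1e-12  # residual tolerance on sigma^2 - g k tanh(kH), relative


@dataclass(frozen=True)
class WaveParameters:
    """Monochromatic forcing-wave parameters.

    Parameters
    ----------
    a : float
        Wave amplitude [m] (half the wave height).
    T : float
        Wave period [s].
    g, rho, f_w : float
        Gravitational acceleration [m/s^2], water density [kg/m^3] and the
        dimensionless wave friction factor (assumed constant).
    """

    a: float
    T: float
    g: float = GRAVITY
    rho: float = RHO_SEAWATER
    f_w: float = FRICTION_FACTOR

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"wave amplitude must be >= 0, got a={self.a}")
        if self.T <= 0:
            raise ValueError(f"wave period must be > 0, got T={self.T}")
        for name in ("g", "rho", "f_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def sigma(self) -> float:
        """Angular frequency 2*pi/T [rad/s]."""
        return 2.0 * math.pi / self.T


@dataclass(frozen=True)
class DispersionSolution:
    """Positive root of the linear dispersion relation at one (T, H)."""

    kappa: float  #: wavenumber [rad/m]
    lam: float  #: wavelength 2*pi/kappa [m]
    H: float  #: water depth [m]
    regime_tag: str = field(default="intermediate")  #: deep / intermediate / shallow


@dataclass(frozen=True)
class BottomKinematics:
    """Near-bed orbital motion and wave-averaged bed shear stress."""

    A_b: float  #: near-bed orbital amplitude [m]
    U_b: float  #: near-bed orbital velocity amplitude [m/s]
    tau_b: float  #: time-averaged bed shear stress 0.5*rho*f_w*U_b^2 [Pa]


def _regime(kappa: float, H: float) -> str:
    kH = kappa * H
    if kH > math.pi:
        return "deep"
    if kH < math.pi / 10.0:
        return "shallow"
    return "intermediate"


def solve_dispersion(T: float, H: float, g: float = GRAVITY) -> DispersionSolution:
    """Solve sigma^2 = g*kappa*tanh(kappa*H) for the unique positive kappa.

    Uses bracketed Brent root-finding; the upper bracket is a safe multiple
    of the deep-water wavenumber inflated by the shallow-water estimate, so
    the root is always enclosed.
    """
    if T <= 0 or H <= 0:
        raise ValueError(f"T and H must be > 0, got T={T}, H={H}")
    sigma = 2.0 * math.pi / T
    k_deep = sigma * sigma / g
    hi = 10.0 * k_deep * (1.0 + 1.0 / math.tanh(min(k_deep * H, 50.0)))

    def residual(k: float) -> float:
        return sigma * sigma - g * k * math.tanh(k * H)

    kappa = brentq(residual, 1e-12, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    rel = abs(residual(kappa)) / (sigma * sigma)
    if rel > 1e-10:
        raise RuntimeError(
            f"dispersion root did not converge on bracket (1e-12, {hi:.3g}): "
            f"relative residual {rel:.3g}"
        )
    return DispersionSolution(kappa=kappa, lam=2.0 * math.pi / kappa, H=H,
                              regime_tag=_regime(kappa, H))


def deep_water_wavelength(T: float, g: float = GRAVITY) -> float:
    """Deep-water wavelength g*T^2/(2*pi) [m]."""
    if T < 0:
        raise ValueError(f"wave period must be >= 0, got T={T}")
    return g * T * T / (2.0 * math.pi)


def shoal_wavelength(lam_inf: float, H: float) -> float:
    """Shoal a deep-water wavelength to depth H.

    Solves the fixed point of lam = lam_inf * tanh(2*pi*H/lam), the
    stationary-frequency form of the dispersion relation. Converged to
    |d lam| < 1e-10 m by damped fixed-point iteration (the map is a
    contraction for the physical root).
    """
    if lam_inf <= 0 or H <= 0:
        raise ValueError(f"lam_inf and H must be > 0, got {lam_inf}, {H}")
    lam = lam_inf * math.tanh(math.sqrt(2.0 * math.pi * H / lam_inf))
    for _ in range(10_000):
        new = lam_inf * math.tanh(2.0 * math.pi * H / lam)
        if abs(new - lam) < 1e-10:
            return new
        lam = 0.5 * (lam + new)
    raise RuntimeError(
        f"shoaling fixed point did not converge for lam_inf={lam_inf}, H={H}"
    )


def bottom_kinematics(
    Hs: float,
    T: float,
    kappa: float,
    H: float,
    rho: float = RHO_SEAWATER,
    f_w: float = FRICTION_FACTOR,
    g: float = GRAVITY,
) -> BottomKinematics:
    """Near-bed orbital amplitude/velocity and wave-averaged bed shear stress.

    A_b = Hs / (2 sinh(kappa H)), U_b = 2 pi A_b / T,
    tau_b = 0.5 rho f_w U_b^2.

    The (T, kappa, H) triple must satisfy the dispersion relation; an
    inconsistent triple raises ``ValueError``.
    """
    if Hs < 0:
        raise ValueError(f"significant wave height must be >= 0, got {Hs}")
    sigma = 2.0 * math.pi / T
    rel = abs(sigma * sigma - g * kappa * math.tanh(kappa * H)) / (sigma * sigma)
    if rel > 1e-8:
        raise ValueError(
            f"(T={T}, kappa={kappa}, H={H}) violates the dispersion relation "
            f"(relative residual {rel:.3g}); solve_dispersion first"
        )
    A_b = Hs / (2.0 * math.sinh(kappa * H))
    U_b = 2.0 * math.pi * A_b / T
    tau_b = 0.5 * rho * f_w * U_b * U_b
    return BottomKinematics(A_b=A_b, U_b=U_b, tau_b=tau_b)


def basic_wave_fields(wp: WaveParameters, ds: DispersionSolution, H0: float,
                      x, z, t):
    """Analytic basic-state fields of a linear gravity wave over a flat bed.

    eta0 = a cos(kx - st);  phi0 = (s a / k) cosh(k(z+H0))/sinh(kH0) sin(kx - st)
    u0 = dphi0/dx, w0 = dphi0/dz evaluated analytically.

    ``x``, ``z``, ``t`` broadcast like numpy arrays. ``z`` must lie inside
    the water column [-H0, 0].
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z < -H0 - 1e-12) or np.any(z > 1e-12):
        raise ValueError(f"z must lie in [-H0, 0] = [{-H0}, 0]")
    a, sigma, kappa = wp.a, wp.sigma, ds.kappa
    phase = kappa * x - sigma * t
    sinh_kH = math.sinh(kappa * H0)
    cosh_z = np.cosh(kappa * (z + H0))
    sinh_z = np.sinh(kappa * (z + H0))
    eta0 = a * np.cos(phase)
    phi0 = (sigma * a / kappa) * (cosh_z / sinh_kH) * np.sin(phase)
    u0 = sigma * a * (cosh_z / sinh_kH) * np.cos(phase)
    w0 = sigma * a * (sinh_z / sinh_kH) * np.sin(phase)
    return eta0, phi0, u0, w0
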