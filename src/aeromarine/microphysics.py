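"""Aerosol microphysics over the ocean.

Two parameterisations drive the whole exchange budget:

* the dry deposition velocity of a particle to the sea surface, computed with
  a two-layer resistance model of the Williams type: gravitational settling
  acts everywhere, turbulent transfer carries particles through the constant
  flux layer, and surface uptake happens in parallel over the undisturbed
  (smooth) sea surface and over the wind-dependent whitecap (broken) fraction;

* the Gong (2003) sea-spray source function, whose integral over droplet
  volume gives the "spray volume velocity" -- the volume of seawater ejected
  into the air per unit sea surface and time.

Radii in the source function follow its native convention of radius at 80 %
relative humidity (r80).  The deposition diameter of a microbial class is its
measured mean diameter; no hygroscopic growth is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate

from .core_io import MeteoState, ParticleClass

__all__ = [
    "DepositionParams",
    "SpraySourceParams",
    "air_viscosity",
    "air_density",
    "mean_free_path",
    "slip_correction",
    "settling_velocity",
    "deposition_velocity",
    "spray_number_flux_density",
    "spray_volume_velocity",
]

G = 9.81                  # m s^-2
K_BOLTZMANN = 1.380649e-23  # J K^-1
R_DRY_AIR = 287.05        # J kg^-1 K^-1


def air_viscosity(T: float) -> float:
    """Dynamic viscosity of air (Pa s) by Sutherland's law."""
    return 1.716e-5 * (T / 273.15) ** 1.5 * (273.15 + 110.4) / (T + 110.4)


def air_density(T: float, P: float) -> float:
    """Dry-air density (kg m^-3) from the ideal gas law; P in Pa."""
    return P / (R_DRY_AIR * T)


def mean_free_path(T: float, P: float,
                   lambda_ref: float = 0.0665e-6,
                   T_ref: float = 298.15, P_ref: float = 101325.0) -> float:
    """Mean free path of air molecules (m), scaled from reference conditions
    as lambda(T, P) = lambda_ref (T/T_ref)(P_ref/P)."""
    return lambda_ref * (T / T_ref) * (P_ref / P)


def slip_correction(diameter: float, T: float, P: float) -> float:
    """Cunningham slip correction factor (dimensionless, >= 1).

    Uses the classical coefficient set 1.257 / 0.4 / 1.1 with the
    temperature- and pressure-scaled mean free path.  diameter in m, T in K,
    P in Pa.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    kn2 = 2.0 * mean_free_path(T, P) / d  # 2 Kn = 2 lambda / d
    out = 1.0 + kn2 * (1.257 + 0.4 * np.exp(-1.1 / kn2))
    return float(out) if np.isscalar(diameter) else out


def settling_velocity(particle: ParticleClass, meteo: MeteoState) -> float:
    """Stokes gravitational settling velocity with slip correction (m s^-1).

    v_g = rho_p d^2 g Cc / (18 mu(T)).  Valid for the micron-size range of
    microbial aerosols; a warning is not raised below ~50 um where the Stokes
    regime holds.
    """
    cc = slip_correction(particle.diameter, meteo.T, meteo.P)
    return (particle.density * particle.diameter ** 2 * G * cc
            / (18.0 * air_viscosity(meteo.T)))


@dataclass(frozen=True)
class DepositionParams:
    """Constants of the two-layer ocean-surface deposition model.

    drag_coefficient
        Neutral 10-m drag coefficient C_D of the sea surface; the friction
        velocity is u* = sqrt(C_D) u10 and the aerodynamic transfer velocity
        k_a = C_D u10.
    whitecap_coeff, whitecap_exponent
        Broken-surface (whitecap) area fraction alpha = c u10^e, capped at 1.
    brownian_exponent
        Exponent m of the Schmidt-number term Sc^-m in the smooth-surface
        transfer velocity.
    """

    drag_coefficient: float = 1.3e-3
    von_karman: float = 0.4
    whitecap_coeff: float = 1.7e-6
    whitecap_exponent: float = 3.75
    brownian_exponent: float = 0.5

    def whitecap_fraction(self, u10: float) -> float:
        return min(self.whitecap_coeff * u10 ** self.whitecap_exponent, 1.0)


def _two_layer(k_a: float, k_s: float, v_g: float) -> float:
    # series combination of two transfer layers with settling through both
    return (k_a + v_g) * (k_s + v_g) / (k_a + k_s + v_g)


def deposition_velocity(particle: ParticleClass, meteo: MeteoState,
                        params: DepositionParams | None = None) -> float:
    """Dry deposition velocity to the sea surface (m s^-1).

    Smooth-surface uptake combines Brownian diffusion (Sc^-1/2) and inertial
    impaction (10^(-3/St)); over the whitecap fraction the bursting-bubble
    surface takes particles up at the friction velocity.  Always >=
    the gravitational settling velocity, and reduces to it at u10 = 0.
    """
    params = params or DepositionParams()
    v_g = settling_velocity(particle, meteo)
    u10 = meteo.u10
    if u10 <= 0:
        return v_g
    cd = params.drag_coefficient
    u_star = math.sqrt(cd) * u10
    k_a = cd * u10
    nu = air_viscosity(meteo.T) / air_density(meteo.T, meteo.P)
    d_b = (K_BOLTZMANN * meteo.T * slip_correction(particle.diameter, meteo.T, meteo.P)
           / (3.0 * math.pi * air_viscosity(meteo.T) * particle.diameter))
    sc = nu / d_b
    st = v_g * u_star ** 2 / (G * nu)
    impaction = 10.0 ** (-3.0 / st) if st > 0 else 0.0
    k_smooth = (u_star ** 2 / u10) * (sc ** -params.brownian_exponent
                                      + impaction)
    k_broken = u_star
    alpha = params.whitecap_fraction(u10)
    return ((1.0 - alpha) * _two_layer(k_a, k_smooth, v_g)
            + alpha * _two_layer(k_a, k_broken, v_g))


@dataclass(frozen=True)
class SpraySourceParams:
    """Gong (2003) source-function settings.

    r_min, r_max : integration bounds in um (r80 convention).
    theta : Gong's adjustable shape parameter for the sub-micron branch.
    n_quad : log-radius panels for the fallback midpoint rule.
    """

    r_min: float = 0.2
    r_max: float = 10.0
    theta: float = 30.0
    seawater_density: float = 1025.0   # kg m^-3, for mass conversions
    n_quad: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.r_min < self.r_max:
            raise ValueError("need 0 < r_min < r_max")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


def spray_number_flux_density(r80, u10: float,
                              params: SpraySourceParams | None = None):
    """Sea-spray number flux density dF/dr80 (particles m^-2 s^-1 um^-1).

    Gong (2003) modification of the Monahan whitecap source function::

        dF/dr = 1.373 u10^3.41 r^-A (1 + 0.057 r^3.45) 10^(1.607 exp(-B^2))
        A = 4.7 (1 + theta r)^(-0.017 r^-1.44)
        B = (0.433 - log10 r) / 0.433

    r80 in um and within [r_min, r_max].
    """
    params = params or SpraySourceParams()
    r = np.asarray(r80, dtype=float)
    if np.any((r < params.r_min) | (r > params.r_max)):
        raise ValueError(f"r80 outside [{params.r_min}, {params.r_max}] um")
    out = _gong_dF_dr(r, u10, params.theta)
    return float(out) if np.isscalar(r80) else out


def _gong_dF_dr(r, u10, theta):
    a_exp = 4.7 * (1.0 + theta * r) ** (-0.017 * r ** -1.44)
    b = (0.433 - np.log10(r)) / 0.433
    return (1.373 * u10 ** 3.41 * r ** -a_exp
            * (1.0 + 0.057 * r ** 3.45) * 10.0 ** (1.607 * np.exp(-b ** 2)))


@lru_cache(maxsize=32)
def _unit_volume_flux(r_min: float, r_max: float, theta: float) -> float:
    """Integral of (dF/dr at u10 = 1) (4/3) pi r^3 over [r_min, r_max],
    radii converted to metres in the volume factor.  Adaptive quadrature in
    log-radius with a midpoint-rule cross-check."""
    def integrand(lr):
        r = math.exp(lr)
        return (_gong_dF_dr(np.asarray(r), 1.0, theta)
                * (4.0 / 3.0) * math.pi * (r * 1e-6) ** 3 * r)

    val, err = integrate.quad(integrand, math.log(r_min), math.log(r_max),
                              limit=200, epsabs=0.0, epsrel=1e-10)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise ArithmeticError(
            f"spray-flux quadrature did not converge (value={val}, err={err})")
    return val


def spray_volume_velocity(meteo: MeteoState,
                          params: SpraySourceParams | None = None) -> float:
    """Total seawater volume flux of spray, V_T (m^3 m^-2 s^-1).

    V_T = integral of dF/dr80 (4/3) pi r^3 dr over [r_min, r_max].  Wind
    speed factors out of the Gong formula, so V_T scales exactly as
    u10^3.41.
    """
    params = params or SpraySourceParams()
    if meteo.u10 <= 0:
        return 0.0
    base = _unit_volume_flux(params.r_min, params.r_max, params.theta)
    return base * meteo.u10 ** 3.41
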