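"""Air-sea microbial flux equations and the steady-state oceanic contribution.

Dry deposition removes cells from the boundary layer at Fd = v_d C_air;
sea spray injects them at Fs = V_T C_water.  Setting Fd = Fs defines the
equilibrium ("oceanic contribution") air concentration C_eq = V_T C_water /
v_d, the abundance the local ocean alone can sustain.  Observed abundance
minus C_eq is the advected -- mostly terrestrial -- excess; it is kept signed,
since stations can sit below equilibrium.  Deposition is positive in the net
flux convention used here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import MeteoState, ParticleClass
from .microphysics import (DepositionParams, SpraySourceParams,
                           deposition_velocity, spray_volume_velocity)

__all__ = [
    "FluxSet",
    "dry_deposition_flux",
    "spray_cell_flux",
    "equilibrium_air_concentration",
    "terrestrial_excess",
    "wet_deposition_flux",
    "cells_to_carbon",
    "station_fluxes",
]

#: Default scavenging ratio for wet deposition (mid-range for micron aerosol).
DEFAULT_SCAVENGING_RATIO = 500.0

MM_PER_H_TO_M_PER_S = 1.0e-3 / 3600.0
GRAMS_PER_TG = 1.0e12
SECONDS_PER_YEAR = 365.25 * 86400.0


@dataclass(frozen=True)
class FluxSet:
    """Per-station, per-particle-class exchange summary (all SI, s^-1)."""

    v_d: float                  # m s^-1
    v_spray: float              # m^3 m^-2 s^-1
    f_dry: float                # cells m^-2 s^-1
    f_spray: float              # cells m^-2 s^-1
    f_wet: float                # cells m^-2 s^-1
    c_air_equilibrium: float    # cells m^-3
    excess: float               # cells m^-3, signed

    @property
    def f_net(self) -> float:
        """Net flux, deposition positive: f_dry + f_wet - f_spray."""
        return self.f_dry + self.f_wet - self.f_spray


def dry_deposition_flux(c_air: float, v_d: float) -> float:
    """Dry deposition flux Fd = v_d C_air (cells m^-2 s^-1)."""
    if c_air < 0 or v_d < 0:
        raise ValueError("c_air and v_d must be >= 0")
    return v_d * c_air


def spray_cell_flux(c_water: float, v_spray: float) -> float:
    """Spray emission flux Fs = V_T C_water (cells m^-2 s^-1)."""
    if c_water < 0 or v_spray < 0:
        raise ValueError("c_water and v_spray must be >= 0")
    return v_spray * c_water


def equilibrium_air_concentration(
        c_water: float, meteo: MeteoState, particle: ParticleClass,
        dep_params: DepositionParams | None = None,
        spray_params: SpraySourceParams | None = None) -> float:
    """Steady-state air concentration C_eq = V_T C_water / v_d (cells m^-3).

    At C_air = C_eq the dry deposition flux exactly balances the spray
    emission flux for the given water abundance and meteorology.
    """
    if c_water < 0:
        raise ValueError("c_water must be >= 0")
    v_d = deposition_velocity(particle, meteo, dep_params)
    if v_d <= 0:
        raise ZeroDivisionError(
            "deposition velocity is 0; equilibrium undefined")
    return spray_volume_velocity(meteo, spray_params) * c_water / v_d


def terrestrial_excess(c_air_observed: float, c_eq: float) -> float:
    """Signed excess above (or deficit below) the oceanic equilibrium."""
    return c_air_observed - c_eq


def wet_deposition_flux(c_air: float, precip: float,
                        scavenging_ratio: float = DEFAULT_SCAVENGING_RATIO
                        ) -> float:
    """Wet deposition flux W C_air p (cells m^-2 s^-1); precip in mm h^-1.

    Generic scavenging-ratio model: rain of rate p removes aerosol with a
    dimensionless washout efficiency W relative to the air concentration.
    """
    if c_air < 0 or precip < 0 or scavenging_ratio < 0:
        raise ValueError("inputs must be >= 0")
    return scavenging_ratio * c_air * precip * MM_PER_H_TO_M_PER_S


def cells_to_carbon(n_cells: float, particle: ParticleClass,
                    teragrams: bool = False) -> float:
    """Convert a cell count to carbon mass in g C (or Tg C)."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    grams = n_cells * particle.carbon_per_cell
    return grams / GRAMS_PER_TG if teragrams else grams


def station_fluxes(c_air: float, c_water: float, meteo: MeteoState,
                   particle: ParticleClass,
                   dep_params: DepositionParams | None = None,
                   spray_params: SpraySourceParams | None = None,
                   scavenging_ratio: float = DEFAULT_SCAVENGING_RATIO
                   ) -> FluxSet:
    """Full exchange budget for one station and particle class."""
    v_d = deposition_velocity(particle, meteo, dep_params)
    v_spray = spray_volume_velocity(meteo, spray_params)
    c_eq = v_spray * c_water / v_d
    return FluxSet(
        v_d=v_d,
        v_spray=v_spray,
        f_dry=dry_deposition_flux(c_air, v_d),
        f_spray=spray_cell_flux(c_water, v_spray),
        f_wet=wet_deposition_flux(c_air, meteo.precip, scavenging_ratio),
        c_air_equilibrium=c_eq,
        excess=terrestrial_excess(c_air, c_eq),
    )
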