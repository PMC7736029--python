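"""Moist-air property calculations.

All internal quantities are SI: kelvin, pascal, kilogram, second. Specific
humidity ``Y`` is mass of water vapour per mass of *dry* gas, the natural
bookkeeping variable for an open-loop dryer because the dry-gas mass flow is
conserved from inlet to exhaust while water is picked up along the way.

Saturation vapour pressure uses a Magnus-form correlation with the Buck
coefficients, accurate to well under 0.5% over 0-130 degC, so no steam
tables are needed at run time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MoistAirState",
    "GasProperties",
    "AIR_WATER",
    "saturation_vapor_pressure",
    "specific_humidity_from_rh",
    "rh_from_specific_humidity",
    "humidity_gain",
    "evaporative_cooling",
]

# Enhanced Magnus-form (Buck) coefficients, Celsius form, output in Pa:
# p_sat = A exp((B - t/D) t / (C + t))
_MAGNUS_A = 611.21
_MAGNUS_B = 18.678
_MAGNUS_C = 257.14
_MAGNUS_D = 234.5

#: valid temperature range of the correlation, kelvin
_T_MIN = 173.15
_T_MAX = 473.15


def saturation_vapor_pressure(temperature: float) -> float:
    """Saturation vapour pressure of water over a flat surface, Pa.

    Magnus form with the Buck coefficients,
    ``p_sat = A exp((B - t/D) t / (C + t))`` with ``t`` in Celsius.

    Parameters
    ----------
    temperature : float
        Dry-bulb temperature in kelvin; must lie in (173.15, 473.15) K.
    """
    if not (_T_MIN < temperature < _T_MAX):
        raise ValueError(
            f"temperature {temperature!r} K outside the valid range "
            f"({_T_MIN} K, {_T_MAX} K) of the vapour-pressure correlation"
        )
    t_c = temperature - 273.15
    return _MAGNUS_A * math.exp((_MAGNUS_B - t_c / _MAGNUS_D) * t_c / (_MAGNUS_C + t_c))


def specific_humidity_from_rh(
    temperature: float,
    relative_humidity: float,
    total_pressure: float,
    molar_mass_ratio: float = 0.62198,
) -> float:
    """Specific humidity Y (kg water / kg dry gas) from relative humidity.

    ``Y = ratio * p_v / (p - p_v)`` with ``p_v = RH * p_sat(T)``.
    """
    if not 0.0 <= relative_humidity <= 1.0:
        raise ValueError(f"relative humidity {relative_humidity!r} outside [0, 1]")
    if total_pressure <= 0:
        raise ValueError("total pressure must be positive")
    p_v = relative_humidity * saturation_vapor_pressure(temperature)
    if p_v >= total_pressure:
        raise ValueError(
            "vapour partial pressure >= total pressure: infeasible moist-air state"
        )
    return molar_mass_ratio * p_v / (total_pressure - p_v)


def rh_from_specific_humidity(
    temperature: float,
    specific_humidity: float,
    total_pressure: float,
    molar_mass_ratio: float = 0.62198,
) -> float:
    """Relative humidity from specific humidity; exact algebraic inverse.

    May return values above 1 for supersaturated states (condensation risk in
    the cyclone/filter); callers decide what to do with them, nothing is
    clipped here.
    """
    if specific_humidity < 0:
        raise ValueError("specific humidity must be non-negative")
    p_v = total_pressure * specific_humidity / (molar_mass_ratio + specific_humidity)
    return p_v / saturation_vapor_pressure(temperature)


@dataclass(frozen=True)
class MoistAirState:
    """One point on the psychrometric chart.

    Attributes
    ----------
    dry_bulb_temperature : float, kelvin
    specific_humidity : float, kg water vapour per kg dry gas
    total_pressure : float, Pa
    relative_humidity : float
        Derived from the other three fields on construction; may exceed 1
        (supersaturation), in which case :attr:`supersaturated` is set.
    """

    dry_bulb_temperature: float
    specific_humidity: float
    total_pressure: float = 101325.0
    relative_humidity: float = field(init=False)

    def __post_init__(self) -> None:
        if self.specific_humidity < 0:
            raise ValueError("specific humidity must be non-negative")
        if self.total_pressure <= 0:
            raise ValueError("total pressure must be positive")
        rh = rh_from_specific_humidity(
            self.dry_bulb_temperature, self.specific_humidity, self.total_pressure
        )
        object.__setattr__(self, "relative_humidity", rh)

    @property
    def supersaturated(self) -> bool:
        return self.relative_humidity > 1.0

    @classmethod
    def from_rh(
        cls,
        dry_bulb_temperature: float,
        relative_humidity: float,
        total_pressure: float = 101325.0,
    ) -> "MoistAirState":
        y = specific_humidity_from_rh(
            dry_bulb_temperature, relative_humidity, total_pressure
        )
        return cls(dry_bulb_temperature, y, total_pressure)

    def to_dict(self) -> dict:
        return {
            "dry_bulb_temperature_K": self.dry_bulb_temperature,
            "specific_humidity_kg_kg": self.specific_humidity,
            "total_pressure_Pa": self.total_pressure,
            "relative_humidity": self.relative_humidity,
            "supersaturated": self.supersaturated,
        }


@dataclass(frozen=True)
class GasProperties:
    """Thermophysical constants of the drying gas / vapour pair.

    Defaults are dry air + water vapour around ambient conditions.
    """

    dry_gas_heat_capacity: float = 1006.0  # J/(kg K)
    vapor_heat_capacity: float = 1860.0  # J/(kg K)
    latent_heat_vaporization: float = 2.36e6  # J/kg, ~60 degC
    molar_mass_ratio: float = 0.62198  # water / dry air

    def __post_init__(self) -> None:
        for name in (
            "dry_gas_heat_capacity",
            "vapor_heat_capacity",
            "latent_heat_vaporization",
            "molar_mass_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if abs(self.molar_mass_ratio - 0.622) > 0.05:
            raise ValueError(
                "molar_mass_ratio far from 0.622: not a water/air-like pair"
            )


#: default water-in-air property set
AIR_WATER = GasProperties()


def humidity_gain(
    inlet: MoistAirState,
    water_evaporation_rate: float,
    dry_gas_mass_flow: float,
) -> MoistAirState:
    """Exhaust-side state after picking up evaporated water.

    Pure mass bookkeeping: ``Y_out = Y_in + m_evap / m_dry_gas``; temperature
    is left unchanged (see :func:`evaporative_cooling` for the energy side).
    """
    if dry_gas_mass_flow <= 0:
        raise ValueError("dry gas mass flow must be positive")
    if water_evaporation_rate < 0:
        raise ValueError("evaporation rate must be non-negative")
    y_out = inlet.specific_humidity + water_evaporation_rate / dry_gas_mass_flow
    return MoistAirState(inlet.dry_bulb_temperature, y_out, inlet.total_pressure)


def evaporative_cooling(
    inlet: MoistAirState,
    gas: GasProperties,
    water_evaporation_rate: float,
    dry_gas_mass_flow: float,
) -> float:
    """Adiabatic temperature drop (K) of the gas due to solvent evaporation.

    ``dT = m_evap * dH_vap / (m_gas * cp_humid)`` with the humid heat capacity
    evaluated at the inlet humidity, ``cp_humid = cp_dry + Y_in * cp_vapor``.
    """
    if dry_gas_mass_flow <= 0:
        raise ValueError("dry gas mass flow must be positive")
    if water_evaporation_rate < 0:
        raise ValueError("evaporation rate must be non-negative")
    cp_humid = (
        gas.dry_gas_heat_capacity + inlet.specific_humidity * gas.vapor_heat_capacity
    )
    return (
        water_evaporation_rate
        * gas.latent_heat_vaporization
        / (dry_gas_mass_flow * cp_humid)
    )
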