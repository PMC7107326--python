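"""Dissolved-oxygen unit conversions for seawater.

Oxygen is carried through the pipeline as % air saturation; conversions to
kPa, mL O2 L^-1 and mg L^-1 go through the oxygen-solubility relation of
Garcia & Gordon (1992, Benson–Krause fit constants) and the water vapour
pressure of seawater. All conversions are exact inverses of each other at
fixed temperature/salinity/pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UnitContext", "o2_solubility_ml_per_l", "convert_oxygen_units", "OXYGEN_UNITS"]

OXYGEN_UNITS = ("pct_airsat", "kPa", "mlO2_per_L", "mg_per_L")

# mole fraction of O2 in dry air
_X_O2 = 0.20946
# mass of O2 per volume at STP: 31.9988 g/mol / 22.3916 L/mol
_MG_PER_ML_O2 = 1.42905

# Garcia & Gordon (1992) combined-fit coefficients, Benson & Krause data,
# solubility in mL(STP) L^-1 as a function of scaled temperature and salinity.
_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_B = (-0.00624523, -0.00737614, -0.0103410, -0.00817083)
_C0 = -4.88682e-7


@dataclass(frozen=True)
class UnitContext:
    """Physical conditions a conversion is evaluated at."""

    temperature_C: float
    salinity_psu: float = 34.0
    pressure_atm: float = 1.0

    def __post_init__(self):
        if not (-2.0 <= self.temperature_C <= 40.0):
            raise ValueError(f"temperature {self.temperature_C} outside [-2, 40] C")
        if not (0.0 <= self.salinity_psu <= 42.0):
            raise ValueError(f"salinity {self.salinity_psu} outside [0, 42]")


def o2_solubility_ml_per_l(temperature_C: float, salinity_psu: float) -> float:
    """Oxygen concentration (mL O2 L^-1) of air-saturated water at 1 atm."""
    ts = np.log((298.15 - temperature_C) / (273.15 + temperature_C))
    lnc = sum(a * ts**i for i, a in enumerate(_A))
    lnc += salinity_psu * sum(b * ts**i for i, b in enumerate(_B))
    lnc += _C0 * salinity_psu**2
    return float(np.exp(lnc))


def _vapor_pressure_kPa(temperature_C: float, salinity_psu: float) -> float:
    # Green & Carritt (1967) saturation vapour pressure over seawater, in atm
    t_k = temperature_C + 273.15
    p_atm = np.exp(
        18.1973 * (1 - 373.16 / t_k)
        + 3.1813e-7 * (1 - np.exp(26.1205 * (1 - t_k / 373.16)))
        - 1.8726e-2 * (1 - np.exp(8.03945 * (1 - 373.16 / t_k)))
        + 5.02802 * np.log(373.16 / t_k)
    ) * (1 - 5.37e-4 * salinity_psu)
    return float(p_atm * 101.325)


def _po2_airsat_kPa(ctx: UnitContext) -> float:
    """Partial pressure of O2 (kPa) in water at 100% air saturation."""
    p_bar = ctx.pressure_atm * 101.325
    return _X_O2 * (p_bar - _vapor_pressure_kPa(ctx.temperature_C, ctx.salinity_psu))


def convert_oxygen_units(value: float, from_unit: str, to_unit: str, ctx: UnitContext) -> float:
    """Convert a dissolved-oxygen value between the supported units.

    Supported units: % air saturation, kPa (partial pressure), mL O2 L^-1,
    mg O2 L^-1. Conversion goes through % air saturation as the pivot, so any
    round trip returns the input to floating-point precision.
    """
    if from_unit not in OXYGEN_UNITS:
        raise ValueError(f"unknown oxygen unit {from_unit!r}")
    if to_unit not in OXYGEN_UNITS:
        raise ValueError(f"unknown oxygen unit {to_unit!r}")
    if value < 0:
        raise ValueError("oxygen value must be >= 0")
    if from_unit == to_unit:
        return float(value)

    c_sat = o2_solubility_ml_per_l(ctx.temperature_C, ctx.salinity_psu) * ctx.pressure_atm
    po2_sat = _po2_airsat_kPa(ctx)

    if from_unit == "pct_airsat":
        pct = value
    elif from_unit == "kPa":
        pct = value / po2_sat * 100.0
    elif from_unit == "mlO2_per_L":
        pct = value / c_sat * 100.0
    else:  # mg_per_L
        pct = value / _MG_PER_ML_O2 / c_sat * 100.0

    if to_unit == "pct_airsat":
        return float(pct)
    if to_unit == "kPa":
        return float(pct / 100.0 * po2_sat)
    if to_unit == "mlO2_per_L":
        return float(pct / 100.0 * c_sat)
    return float(pct / 100.0 * c_sat * _MG_PER_ML_O2)
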