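"""Oxygen unit conversions for aquatic respirometry.

Converts between % air saturation, oxygen partial pressure (kPa) and
dissolved-oxygen concentration (umol/L) as functions of temperature,
salinity and barometric pressure, so chamber PO2 decline slopes (kPa/h)
can be expressed as oxygen uptake rates (umol O2/h).

The empirical fits used are the de-facto standards behind respirometry
software:

* seawater vapour pressure: Green & Carritt (1967), J. Mar. Res. 25.
* O2 solubility at air equilibrium: Benson & Krause (1984) as refit by
  Garcia & Gordon (1992), Limnol. Oceanogr. 37(6), "combined fit"
  coefficients in cm3 dm-3 (check value 6.315 mL/L at 10 degC, 35 psu).

Both coefficient sets are module-level constants so alternates can be
swapped by passing explicit ``coefficients=`` arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "WaterConditions",
    "water_vapour_pressure_kpa",
    "po2_at_saturation",
    "percent_sat_to_kpa",
    "kpa_to_percent_sat",
    "o2_saturation_concentration",
    "solubility_per_kpa",
]

#: Standard atmosphere in kPa.
ATM_KPA = 101.325

#: Real-gas molar volume of O2 at STP, mL per mmol (Garcia & Gordon 1992).
O2_MOLAR_VOLUME_ML_PER_MMOL = 22.3916

#: Green & Carritt (1967) seawater vapour-pressure coefficients
#: (ln p[atm] = a0 + a1*(100/T) + a2*ln(T/100) + a3*S, T in kelvin).
GREEN_CARRITT_COEFFS = (24.4543, -67.4509, -4.8489, -0.000544)

#: Garcia & Gordon (1992) Benson-Krause "combined fit", cm3 dm-3 basis.
GARCIA_GORDON_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
GARCIA_GORDON_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
GARCIA_GORDON_C0 = -4.88682e-7

_TEMP_RANGE = (0.0, 40.0)
_SAL_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class WaterConditions:
    """Water-column state needed for oxygen unit conversions.

    Parameters
    ----------
    temperature_c : float
        Water temperature, degrees Celsius, in [0, 40].
    salinity_psu : float
        Practical salinity, in [0, 45].
    pressure_kpa : float
        Barometric pressure at the water surface (default one atmosphere).
    o2_fraction : float
        Mole fraction of oxygen in dry air (default 0.2095).
    """

    temperature_c: float
    salinity_psu: float
    pressure_kpa: float = ATM_KPA
    o2_fraction: float = 0.2095

    def __post_init__(self) -> None:
        lo, hi = _TEMP_RANGE
        if not lo <= self.temperature_c <= hi:
            raise DomainError(
                f"temperature_c={self.temperature_c} outside [{lo}, {hi}]"
            )
        lo, hi = _SAL_RANGE
        if not lo <= self.salinity_psu <= hi:
            raise DomainError(
                f"salinity_psu={self.salinity_psu} outside [{lo}, {hi}]"
            )
        if not self.pressure_kpa > 0:
            raise DomainError(f"pressure_kpa={self.pressure_kpa} must be > 0")
        if not 0.0 < self.o2_fraction < 1.0:
            raise DomainError(f"o2_fraction={self.o2_fraction} outside (0, 1)")


def water_vapour_pressure_kpa(
    temperature_c: float,
    salinity_psu: float,
    coefficients: tuple[float, float, float, float] = GREEN_CARRITT_COEFFS,
) -> float:
    """Saturation vapour pressure of seawater in kPa (Green & Carritt 1967)."""
    a0, a1, a2, a3 = coefficients
    t_k = temperature_c + 273.15
    ln_p_atm = a0 + a1 * (100.0 / t_k) + a2 * math.log(t_k / 100.0) + a3 * salinity_psu
    return math.exp(ln_p_atm) * ATM_KPA


def po2_at_saturation(cond: WaterConditions) -> float:
    """Oxygen partial pressure (kPa) of water at air equilibrium.

    ``o2_fraction * (barometric pressure - water vapour pressure)``;
    strictly decreasing in temperature at fixed pressure.
    """
    vp = water_vapour_pressure_kpa(cond.temperature_c, cond.salinity_psu)
    if vp >= cond.pressure_kpa:
        raise DomainError(
            "vapour pressure exceeds barometric pressure; conditions invalid"
        )
    return cond.o2_fraction * (cond.pressure_kpa - vp)


def percent_sat_to_kpa(pct, cond: WaterConditions):
    """Convert % air saturation to PO2 in kPa. Accepts scalars or arrays."""
    pct = np.asarray(pct, dtype=float)
    if np.any(pct < 0):
        raise DomainError("percent air saturation must be >= 0")
    out = pct / 100.0 * po2_at_saturation(cond)
    return out if out.ndim else float(out)


def kpa_to_percent_sat(kpa, cond: WaterConditions):
    """Convert PO2 in kPa to % air saturation. Inverse of percent_sat_to_kpa."""
    kpa = np.asarray(kpa, dtype=float)
    if np.any(kpa < 0):
        raise DomainError("PO2 must be >= 0")
    out = kpa / po2_at_saturation(cond) * 100.0
    return out if out.ndim else float(out)


def o2_saturation_concentration(
    cond: WaterConditions,
    a_coeffs: tuple = GARCIA_GORDON_A,
    b_coeffs: tuple = GARCIA_GORDON_B,
    c0: float = GARCIA_GORDON_C0,
) -> float:
    """Air-equilibrium dissolved O2 concentration in umol per litre.

    Garcia & Gordon (1992) Benson-Krause combined fit (per-litre basis),
    scaled for non-standard barometric pressure by the ratio of dry
    oxygen pressures. Strictly decreasing in both temperature and
    salinity over the valid domain.
    """
    t = cond.temperature_c
    s = cond.salinity_psu
    ts = math.log((298.15 - t) / (273.15 + t))
    ln_c = sum(a * ts**i for i, a in enumerate(a_coeffs))
    ln_c += s * sum(b * ts**i for i, b in enumerate(b_coeffs))
    ln_c += c0 * s * s
    ml_per_l = math.exp(ln_c)
    umol_per_l = ml_per_l / O2_MOLAR_VOLUME_ML_PER_MMOL * 1000.0
    # fit is referenced to 1 atm total pressure at 100 % humidity
    vp = water_vapour_pressure_kpa(t, s)
    if vp >= cond.pressure_kpa:
        raise DomainError(
            "vapour pressure exceeds barometric pressure; conditions invalid"
        )
    pressure_factor = (cond.pressure_kpa - vp) / (ATM_KPA - vp)
    return umol_per_l * pressure_factor


def solubility_per_kpa(cond: WaterConditions) -> float:
    """Oxygen capacitance of the water, umol O2 per litre per kPa.

    Defined as saturation concentration divided by saturation PO2;
    Henry-law linearity is assumed across the 0-32 kPa working range.
    """
    return o2_saturation_concentration(cond) / po2_at_saturation(cond)
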