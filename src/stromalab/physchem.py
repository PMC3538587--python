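"""Physical correction calculators for high-altitude hypersaline microsensor work.

Microsensor O2 data are calibrated against the air-equilibrium concentration of
the overlying water, which depends on temperature, salinity and — at high
altitude — on the reduced barometric pressure. This module collects the small,
pure functions for those corrections:

* barometric pressure factor (ratio of ambient to sea-level pressure),
* practical salinity from conductivity (PSS-78, extrapolated above S = 42),
* O2 solubility (Garcia & Gordon combined fit) and percent air saturation,
* molecular and porosity-corrected (effective) O2 diffusivity,
* PAR energy-to-photon-flux conversion.

All functions are pure and operate on scalars or numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "EnvContext",
    "pressure_factor",
    "salinity_from_conductivity",
    "o2_solubility",
    "air_saturation_reference",
    "percent_air_saturation",
    "o2_diffusivity",
    "effective_diffusivity",
    "par_watts_to_photons",
]

#: Isothermal-atmosphere scale height (m). exp(-z/H) reproduces the pressure
#: ratios 0.66 at 3500 m and 0.95 at 460 m to two decimals.
SCALE_HEIGHT_M = 8434.0

#: Default PAR energy-to-quanta conversion for the solar spectrum, µmol J⁻¹.
PAR_UMOL_PER_J = 4.6

#: Conductivity of standard seawater (S = 35) at 15 °C, mS cm⁻¹ (PSS-78 anchor).
C35_15_0 = 42.914


@dataclass(frozen=True)
class EnvContext:
    """Physical state of the overlying water used by the corrections.

    Parameters
    ----------
    temperature_C : float
        Water temperature in °C.
    salinity_gL : float, optional
        Salinity in g L⁻¹ (treated interchangeably with practical salinity).
    conductivity_mScm : float, optional
        Conductivity in mS cm⁻¹; used to derive salinity when salinity_gL
        is not given.
    altitude_m : float
        Altitude above sea level in m (used for the pressure factor when
        pressure_factor is not given explicitly).
    pressure_factor : float, optional
        Ambient/sea-level barometric pressure ratio; computed from altitude
        when omitted.
    porosity : float
        Volume fraction of porewater, in (0, 1].
    """

    temperature_C: float
    salinity_gL: float | None = None
    conductivity_mScm: float | None = None
    altitude_m: float = 0.0
    pressure_factor: float | None = None
    porosity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError(f"porosity must be in (0, 1], got {self.porosity}")
        if self.altitude_m < 0:
            raise ValueError("altitude_m must be >= 0")
        if self.pressure_factor is not None and not 0.0 < self.pressure_factor <= 1.0:
            raise ValueError("pressure_factor must be in (0, 1]")

    @property
    def salinity(self) -> float:
        """Salinity in g L⁻¹, derived from conductivity if needed."""
        if self.salinity_gL is not None:
            return self.salinity_gL
        if self.conductivity_mScm is not None:
            return salinity_from_conductivity(self.conductivity_mScm, self.temperature_C)
        raise ValueError("EnvContext needs salinity_gL or conductivity_mScm")

    @property
    def pf(self) -> float:
        """Barometric pressure factor, explicit or from altitude."""
        if self.pressure_factor is not None:
            return self.pressure_factor
        return pressure_factor(self.altitude_m)


def pressure_factor(
    altitude_m: float,
    model: Literal["exponential", "isa"] = "exponential",
    scale_height_m: float = SCALE_HEIGHT_M,
) -> float:
    """Ratio of ambient barometric pressure at ``altitude_m`` to sea-level pressure.

    The default isothermal exponential model ``exp(-z/H)`` with H = 8434 m
    matches the conventional values 0.66 at 3500 m and 0.95 at 460 m after
    two-decimal rounding. The International Standard Atmosphere polynomial
    (``model="isa"``) is available for comparison; it gives 0.65 at 3500 m.
    """
    if altitude_m < 0:
        raise ValueError(f"altitude must be >= 0, got {altitude_m}")
    if model == "exponential":
        return math.exp(-altitude_m / scale_height_m)
    if model == "isa":
        # ISA troposphere: T0 = 288.15 K, lapse 6.5 K/km, g M / (R L) = 5.2559
        return (1.0 - 2.25577e-5 * altitude_m) ** 5.25588
    raise ValueError(f"unknown barometric model {model!r}")


# PSS-78 coefficients (conductivity ratio -> practical salinity at 0 dbar)
_PSS_A = (0.0080, -0.1692, 25.3851, 14.0941, -7.0261, 2.7081)
_PSS_B = (0.0005, -0.0056, -0.0066, -0.0375, 0.0636, -0.0144)
_PSS_C = (0.6766097, 2.00564e-2, 1.104259e-4, -6.9698e-7, 1.0031e-9)
_PSS_K = 0.0162


def salinity_from_conductivity(conductivity_mScm: float, temperature_C: float) -> float:
    """Practical salinity from conductivity (mS cm⁻¹) at atmospheric pressure.

    Implements the PSS-78 polynomial on the conductivity ratio
    R = C / C(35, 15, 0). Values above the nominal validity limit S = 42 are a
    plain polynomial extrapolation — adequate here because the brines of
    interest are assumed to share the ionic composition of seawater. The
    result is conventionally reported as g L⁻¹.
    """
    if conductivity_mScm <= 0:
        raise ValueError(f"conductivity must be > 0, got {conductivity_mScm}")
    if not 0.0 <= temperature_C <= 40.0:
        raise ValueError(f"temperature out of range [0, 40] degC: {temperature_C}")
    t = temperature_C
    rt = sum(c * t**i for i, c in enumerate(_PSS_C))
    Rt = (conductivity_mScm / C35_15_0) / rt
    sr = math.sqrt(Rt)
    powers = [sr**i for i in range(6)]
    S = sum(a * p for a, p in zip(_PSS_A, powers))
    dS = (t - 15.0) / (1.0 + _PSS_K * (t - 15.0)) * sum(
        b * p for b, p in zip(_PSS_B, powers)
    )
    return S + dS


def seawater_conductivity(salinity: float, temperature_C: float) -> float:
    """Inverse of :func:`salinity_from_conductivity` (bisection), mS cm⁻¹."""
    from scipy.optimize import brentq

    return float(
        brentq(
            lambda c: salinity_from_conductivity(c, temperature_C) - salinity,
            1e-3,
            300.0,
        )
    )


# Garcia & Gordon (1992) combined fit, Benson & Krause data; returns µmol kg⁻¹.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def _o2_solubility_umol_kg(temperature_C: float, salinity: float) -> float:
    Ts = math.log((298.15 - temperature_C) / (273.15 + temperature_C))
    ln_c = (
        sum(a * Ts**i for i, a in enumerate(_GG_A))
        + salinity * sum(b * Ts**i for i, b in enumerate(_GG_B))
        + _GG_C0 * salinity**2
    )
    return math.exp(ln_c)


def seawater_density(temperature_C: float, salinity: float) -> float:
    """Seawater density at atmospheric pressure (EOS-80 one-atm fit), kg m⁻³."""
    t = temperature_C
    S = salinity
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    A = 8.24493e-1 - 4.0899e-3 * t + 7.6438e-5 * t**2 - 8.2467e-7 * t**3 + 5.3875e-9 * t**4
    B = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    C = 4.8314e-4
    return rho_w + A * S + B * S**1.5 + C * S**2


def o2_solubility(
    temperature_C: float,
    salinity_gL: float,
    density_model: Literal["eos", "unit"] = "eos",
) -> float:
    """Air-equilibrium O2 concentration at sea-level pressure, in µM.

    Uses the Garcia & Gordon combined solubility fit (µmol kg⁻¹) and converts
    to per-litre with the seawater equation-of-state density at (T, S). With
    ``density_model="unit"`` a fixed 1.0 kg L⁻¹ is used instead, which shifts
    results by ~3% at the salinities of interest.
    """
    if not 0.0 <= temperature_C <= 40.0:
        raise ValueError(f"temperature out of range [0, 40] degC: {temperature_C}")
    if salinity_gL < 0:
        raise ValueError("salinity must be >= 0")
    per_kg = _o2_solubility_umol_kg(temperature_C, salinity_gL)
    if density_model == "eos":
        rho_kg_L = seawater_density(temperature_C, salinity_gL) / 1000.0
    elif density_model == "unit":
        rho_kg_L = 1.0
    else:
        raise ValueError(f"unknown density model {density_model!r}")
    return per_kg * rho_kg_L


def air_saturation_reference(env: EnvContext) -> float:
    """100%-air-saturation O2 concentration at ambient pressure, µM.

    The sea-level solubility at (T, S) scaled by the barometric pressure
    factor: ``PF × o2_solubility(T, S)``.
    """
    return env.pf * o2_solubility(env.temperature_C, env.salinity)


def percent_air_saturation(concentration_uM: float, env: EnvContext) -> float:
    """Express an O2 concentration as percent of ambient air saturation."""
    if concentration_uM < 0:
        raise ValueError("concentration must be >= 0")
    ref = air_saturation_reference(env)
    if ref <= 0:
        raise ValueError("air-saturation reference is non-positive")
    return 100.0 * concentration_uM / ref


# Molecular diffusivity of O2 in pure water, 1e-9 m² s⁻¹, 0-40 °C in 5° steps.
# Values follow the standard seawater-microsensor tabulations of the
# Stokes-Einstein-consistent temperature dependence.
_D_O2_TABLE_T = np.arange(0.0, 45.0, 5.0)
_D_O2_TABLE = np.array([1.10, 1.27, 1.45, 1.65, 1.87, 2.10, 2.35, 2.61, 2.89]) * 1e-9

#: Linear salting-out coefficient for gas diffusivity, per salinity unit.
_D_SALINITY_SLOPE = 0.00075


def o2_diffusivity(temperature_C: float, salinity_gL: float = 0.0) -> float:
    """Molecular diffusion coefficient of O2 in water, m² s⁻¹.

    Linear interpolation in a built-in 0-40 °C table with a multiplicative
    salinity correction ``1 - 0.00075 S`` of the Li & Gregory type.
    """
    if not 0.0 <= temperature_C <= 40.0:
        raise ValueError(f"temperature out of range [0, 40] degC: {temperature_C}")
    if salinity_gL < 0:
        raise ValueError("salinity must be >= 0")
    d = float(np.interp(temperature_C, _D_O2_TABLE_T, _D_O2_TABLE))
    return d * (1.0 - _D_SALINITY_SLOPE * salinity_gL)


def effective_diffusivity(D: float, porosity: float) -> float:
    """Effective diffusivity inside the porous sample: D_eff = φ·D."""
    if not 0.0 < porosity <= 1.0:
        raise ValueError(f"porosity must be in (0, 1], got {porosity}")
    return porosity * D


def par_watts_to_photons(
    irradiance_Wm2: float, umol_per_J: float = PAR_UMOL_PER_J
) -> float:
    """Convert PAR irradiance (W m⁻²) to photon flux (µmol photons m⁻² s⁻¹)."""
    if irradiance_Wm2 < 0:
        raise ValueError("irradiance must be >= 0")
    return irradiance_Wm2 * umol_per_J
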