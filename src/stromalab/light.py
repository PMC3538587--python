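"""Spectral attenuation of scalar irradiance and bounded UV extrapolation.

Scalar irradiance E_s(z, λ), normalized to its value at the sample surface,
decays approximately exponentially with depth in a dense microbial sample.
The diffuse attenuation coefficient K(λ) is the negated slope of ln E_s
against depth; the fold attenuation over a depth interval Δz is exp(K Δz).

UV attenuation is rarely measurable directly with fiber-optic microprobes,
but it can be bounded from two visible/NIR wavelengths: 750 nm, where
pigment absorption is negligible and K is dominated by scattering, and
676 nm, the in-vivo Chl a absorption maximum. The model decomposes

    K(λ) = K_scatter(λ) + K_abs(λ),
    K_scatter(λ) = K750 · (750/λ)^n            (power-law scattering),
    K_abs(676)   = K676 − K750 · (750/676)^n   (residual pigment absorption),

and brackets the unknown UV absorption of cellular and detrital matter as a
multiplier range of the 676 nm absorption. The returned interval is the
min/max fold attenuation per mm across the UV band (280-400 nm) and the
absorption-multiplier range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralProfile", "AttenuationModel", "attenuation_coefficient",
           "fold_attenuation", "estimate_uv_attenuation"]


@dataclass
class SpectralProfile:
    """Normalized scalar irradiance E_s(z, λ) with E_s(0, λ) = 1."""

    depths_mm: np.ndarray
    wavelengths_nm: np.ndarray
    irradiance: np.ndarray  # shape (n_depths, n_wavelengths)

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if self.irradiance.shape != (len(self.depths_mm), len(self.wavelengths_nm)):
            raise ValueError("irradiance must be (n_depths, n_wavelengths)")
        if np.any(np.diff(self.depths_mm) <= 0):
            raise ValueError("depths must be strictly increasing")

    def at_wavelength(self, wavelength_nm: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        if abs(self.wavelengths_nm[idx] - wavelength_nm) > 5.0:
            raise ValueError(f"no wavelength within 5 nm of {wavelength_nm}")
        return self.irradiance[:, idx]


@dataclass
class AttenuationModel:
    """Configuration for the two-component UV extrapolation.

    n: power-law exponent of the scattering wavelength dependence.
    absorption_bounds: (low, high) multipliers of the 676 nm pigment
        absorption bracketing the unknown UV absorption.
    uv_band_nm: evaluated UV range; sampled at uv_step_nm.
    """

    n: float = 1.0
    absorption_bounds: tuple[float, float] = (0.5, 2.0)
    uv_band_nm: tuple[float, float] = (280.0, 400.0)
    uv_step_nm: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.absorption_bounds
        if lo < 0 or lo > hi:
            raise ValueError("absorption_bounds must satisfy 0 <= low <= high")
        if self.n < 0:
            raise ValueError("scattering exponent n must be >= 0")


def attenuation_coefficient(
    depths_mm: np.ndarray, irradiance: np.ndarray,
    depth_range_mm: tuple[float, float] | None = None,
) -> float:
    """Diffuse attenuation coefficient K (mm⁻¹) from normalized E_s(z).

    K is the negated least-squares slope of ln E_s against depth, optionally
    restricted to ``depth_range_mm``.
    """
    z = np.asarray(depths_mm, dtype=float)
    e = np.asarray(irradiance, dtype=float)
    if depth_range_mm is not None:
        mask = (z >= depth_range_mm[0]) & (z <= depth_range_mm[1])
        z, e = z[mask], e[mask]
    if len(z) < 3:
        raise ValueError("need >=3 points in the fit range")
    if np.any(e <= 0):
        raise ValueError("irradiance must be positive for log-linear fitting")
    slope = np.polyfit(z, np.log(e), 1)[0]
    return float(-slope)


def fold_attenuation(K_per_mm: float, dz_mm: float = 1.0) -> float:
    """Fold decrease of irradiance over ``dz_mm``: exp(K·Δz)."""
    return float(np.exp(K_per_mm * dz_mm))


def estimate_uv_attenuation(
    K676: float, K750: float, model: AttenuationModel | None = None
) -> tuple[float, float]:
    """Bounded UV fold attenuation per mm from the 676/750 nm pair.

    Returns the (min, max) fold attenuation over 1 mm across the UV band and
    the absorption-bound range. Raises if K676 < K750 (no resolvable pigment
    absorption; the decomposition is inapplicable).
    """
    if model is None:
        model = AttenuationModel()
    if K750 < 0 or K676 < K750:
        raise ValueError("model requires K676 >= K750 >= 0")
    k_abs_676 = K676 - K750 * (750.0 / 676.0) ** model.n
    k_abs_676 = max(k_abs_676, 0.0)
    lam = np.arange(model.uv_band_nm[0], model.uv_band_nm[1] + model.uv_step_nm / 2,
                    model.uv_step_nm)
    k_scatter = K750 * (750.0 / lam) ** model.n
    lo_mult, hi_mult = model.absorption_bounds
    k_low = k_scatter + lo_mult * k_abs_676
    k_high = k_scatter + hi_mult * k_abs_676
    return (fold_attenuation(float(k_low.min())), fold_attenuation(float(k_high.max())))
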