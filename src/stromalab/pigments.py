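"""Pigment quantification from chromatograms, extracts and reflectance cubes.

HPLC elution peaks are converted to pigment mass with

    m = F · A / (e_m · d)

where F is the solvent flow rate (ml min⁻¹), A the time-integrated peak area
(AU·min), e_m the mass extinction coefficient (L g⁻¹ cm⁻¹) at the detection
wavelength and d the detector path length (cm). Phycocyanin is quantified
spectrophotometrically from phosphate-buffer extracts with the standard
two-wavelength (615/652 nm) cyanobacterial equation. Relative Chl a in
hyperspectral reflectance images is mapped with the absorption-valley index
log10(R750/R676).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PigmentSpec", "Chromatogram", "HyperspectralCube", "LayerSection",
    "PIGMENTS", "integrate_peak", "quantify_pigment",
    "phycocyanin_concentration", "chl_index_map", "profile_correlation",
]


@dataclass(frozen=True)
class PigmentSpec:
    name: str
    absorption_max_nm: float
    extinction_L_per_g_cm: float
    retention_window_min: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.extinction_L_per_g_cm <= 0:
            raise ValueError("extinction coefficient must be > 0")


#: Built-in specs with mass extinction coefficients at the absorption maximum.
PIGMENTS: dict[str, PigmentSpec] = {
    "chl_a": PigmentSpec("chl_a", 665.0, 79.95),
    "bchl_a": PigmentSpec("bchl_a", 771.0, 60.0),
    "bchl_c": PigmentSpec("bchl_c", 667.0, 86.0),
}


@dataclass
class Chromatogram:
    """A detector trace: absorbance (AU) against elution time (min)."""

    time_min: np.ndarray
    absorbance_AU: np.ndarray
    flow_rate_ml_min: float = 0.5
    cell_path_cm: float = 1.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.absorbance_AU = np.asarray(self.absorbance_AU, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(~np.isfinite(self.absorbance_AU)):
            raise ValueError("absorbance must be finite")


@dataclass
class HyperspectralCube:
    """Reflectance R(x, z, λ) with a surface line index per x position."""

    x_positions: np.ndarray
    depths_mm: np.ndarray
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray  # (n_x, n_depths, n_wavelengths)
    surface_index: np.ndarray | None = None  # first in-sample depth index per x

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        expected = (len(self.x_positions), len(self.depths_mm), len(self.wavelengths_nm))
        if self.reflectance.shape != expected:
            raise ValueError(f"reflectance must have shape {expected}")
        if self.surface_index is None:
            self.surface_index = np.zeros(len(self.x_positions), dtype=int)

    def band(self, wavelength_nm: float, tol_nm: float = 5.0) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        if abs(self.wavelengths_nm[idx] - wavelength_nm) > tol_nm:
            raise ValueError(f"no wavelength within {tol_nm} nm of {wavelength_nm}")
        return self.reflectance[:, :, idx]


@dataclass
class LayerSection:
    """A sectioned sample layer with its dry weight and pigment masses."""

    top_mm: float
    bottom_mm: float
    dry_weight_g: float
    pigment_mass_ug: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dry_weight_g <= 0:
            raise ValueError("dry weight must be > 0")
        if self.top_mm >= self.bottom_mm:
            raise ValueError("layer top must be above bottom")

    def concentration_ug_per_g(self, pigment: str) -> float:
        return self.pigment_mass_ug[pigment] / self.dry_weight_g


def integrate_peak(
    chrom: Chromatogram,
    window_min: tuple[float, float],
    baseline: str = "linear",
) -> float:
    """Area of an elution peak over a baseline, AU·min (clamped at 0).

    The default baseline is the straight line between the chromatogram values
    at the window endpoints; ``baseline="zero"`` integrates the raw trace.
    """
    t0, t1 = window_min
    mask = (chrom.time_min >= t0) & (chrom.time_min <= t1)
    if mask.sum() < 3:
        raise ValueError("window must contain >=3 samples")
    t = chrom.time_min[mask]
    a = chrom.absorbance_AU[mask]
    if baseline == "linear":
        base = a[0] + (a[-1] - a[0]) * (t - t[0]) / (t[-1] - t[0])
    elif baseline == "zero":
        base = np.zeros_like(a)
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    area = float(np.trapezoid(a - base, t))
    return max(area, 0.0)


def quantify_pigment(
    area_AU_min: float,
    pigment: str | PigmentSpec,
    flow_ml_min: float = 0.5,
    path_cm: float = 1.0,
) -> float:
    """Pigment mass m = F·A/(e_m·d) in µg.

    Units: AU·min × ml min⁻¹ = AU·ml = 10⁻³ AU·L; dividing by e_m·d
    (L g⁻¹) yields 10⁻³ g per unit absorbance, i.e. a factor 1000 to µg.
    """
    if isinstance(pigment, str):
        try:
            spec = PIGMENTS[pigment]
        except KeyError:
            raise ValueError(
                f"unknown pigment {pigment!r}; known: {sorted(PIGMENTS)}"
            ) from None
    else:
        spec = pigment
    if area_AU_min < 0 or flow_ml_min <= 0 or path_cm <= 0:
        raise ValueError("area must be >= 0, flow and path > 0")
    grams = flow_ml_min * 1e-3 * area_AU_min / (spec.extinction_L_per_g_cm * path_cm)
    return grams * 1e6


# Two-wavelength cyanobacterial phycocyanin equation (mg ml⁻¹ in the extract):
# PC = (A615 - 0.474 A652) / 5.34
_PC_CHROMOPHORE_CORR = 0.474
_PC_DENOM = 5.34


def phycocyanin_concentration(
    A615: float,
    A652: float,
    extract_volume_ml: float,
    dry_weight_g: float,
) -> float:
    """Phycocyanin content in µg per g dry weight from extract absorbances.

    Negative computed concentrations (A652-dominated readings) clamp to 0.
    """
    if A615 < 0 or A652 < 0:
        raise ValueError("absorbances must be >= 0")
    if extract_volume_ml <= 0 or dry_weight_g <= 0:
        raise ValueError("extract volume and dry weight must be > 0")
    pc_mg_ml = (A615 - _PC_CHROMOPHORE_CORR * A652) / _PC_DENOM
    pc_mg_ml = max(pc_mg_ml, 0.0)
    total_ug = pc_mg_ml * extract_volume_ml * 1e3
    return total_ug / dry_weight_g


def chl_index_map(cube: HyperspectralCube) -> np.ma.MaskedArray:
    """Relative Chl a index log10(R750/R676) per pixel.

    Pixels above the surface line or with non-positive reflectance at either
    band are masked. The index is invariant to wavelength-independent gain.
    """
    r676 = cube.band(676.0)
    r750 = cube.band(750.0)
    invalid = (r676 <= 0) | (r750 <= 0)
    above_surface = np.zeros_like(invalid)
    for i, s in enumerate(cube.surface_index):
        above_surface[i, :s] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.log10(np.where(invalid, 1.0, r750 / r676))
    return np.ma.masked_array(index, mask=invalid | above_surface)


def profile_correlation(
    depths1_mm: np.ndarray,
    values1: np.ndarray,
    depths2_mm: np.ndarray,
    values2: np.ndarray,
    depth_range_mm: tuple[float, float] | None = None,
    tol_mm: float = 1e-6,
) -> tuple[float, float]:
    """Pearson correlation of two pigment depth profiles on shared bins.

    Profiles are inner-joined on bin centers (within ``tol_mm``), optionally
    restricted to ``depth_range_mm``. Returns (R, two-sided p) from the
    t-distribution with n-2 degrees of freedom.
    """
    d1 = np.asarray(depths1_mm, dtype=float)
    d2 = np.asarray(depths2_mm, dtype=float)
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    pairs = []
    for i, z in enumerate(d1):
        j = np.argmin(np.abs(d2 - z))
        if abs(d2[j] - z) <= tol_mm:
            pairs.append((z, v1[i], v2[j]))
    if depth_range_mm is not None:
        lo, hi = depth_range_mm
        pairs = [p for p in pairs if lo <= p[0] <= hi]
    if len(pairs) < 3:
        raise ValueError("need >=3 paired bins after joining")
    x = np.array([p[1] for p in pairs])
    y = np.array([p[2] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
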