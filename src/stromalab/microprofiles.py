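"""Inversion of microsensor depth profiles into fluxes and volumetric rates.

A steady-state O2 depth profile c(z) measured with a microsensor carries the
full diffusive budget of the photosynthetic layer. Under Fick's law the
interface flux is obtained from the local gradient,

    J = -D_eff dc/dz,

and the volumetric rate of net photosynthesis from the curvature,

    net PS = -D_eff d2c/dz2,

with D_eff = φ·D inside the porous sample and the molecular D in the
diffusive boundary layer (DBL) above it. Depth z increases downward with 0 at
the sample surface; negative depths are in the overlying water.

Derivatives are estimated with local least-squares polynomial (Savitzky-Golay)
windows. Profiles use mm and µM; all physics is done in SI internally.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

MM_TO_M = 1e-3
UM_TO_UMOL_M3 = 1e3  # µM = µmol L⁻¹ -> µmol m⁻³

__all__ = [
    "DepthProfile",
    "RateProfile",
    "FluxSummary",
    "PenetrationResult",
    "load_profile",
    "write_profile",
    "interface_flux",
    "flux_at",
    "net_rate_profile",
    "production_layer",
    "export_partition",
    "penetration_depth",
    "dark_areal_respiration",
    "transient_zone",
]


@dataclass
class DepthProfile:
    """A measured signal on a strictly increasing depth grid.

    depths_mm: depth in mm, 0 at the sample surface, negative above it.
    values: signal in the stated units (µM for O2, pH units, raw for H2S).
    """

    depths_mm: np.ndarray
    values: np.ndarray
    quantity: str = "O2"
    units: str = "uM"
    temperature_C: float | None = None
    light_label: str = ""

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths_mm.ndim != 1 or self.depths_mm.shape != self.values.shape:
            raise ValueError("depths and values must be 1-D arrays of equal length")
        if len(self.depths_mm) < 4:
            raise ValueError(f"profile needs >=4 points, got {len(self.depths_mm)}")
        if np.any(~np.isfinite(self.depths_mm)) or np.any(~np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")
        if np.any(np.diff(self.depths_mm) <= 0):
            raise ValueError("depths must be strictly increasing (duplicates present)")
        if self.quantity.lower() in ("o2", "oxygen") and np.any(self.values < 0):
            raise ValueError("O2 concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.depths_mm)

    def scaled(self, factor: float) -> "DepthProfile":
        """Profile with values multiplied by ``factor`` (linearity checks)."""
        return DepthProfile(
            self.depths_mm.copy(), self.values * factor, self.quantity,
            self.units, self.temperature_C, self.light_label,
        )


@dataclass
class RateProfile:
    """Volumetric net rates (production positive) on interior depth bins."""

    bin_centers_mm: np.ndarray
    net_rate_mmol_m3_s: np.ndarray
    window_pts: int
    poly_order: int
    #: True for bins estimated with one-sided (edge) windows — lower confidence.
    edge_bin: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        if len(self.edge_bin) == 0:
            self.edge_bin = np.zeros(len(self.bin_centers_mm), dtype=bool)
        if np.any(~np.isfinite(self.net_rate_mmol_m3_s)):
            raise ValueError("rates must be finite")

    @property
    def interior(self) -> np.ndarray:
        return ~self.edge_bin


@dataclass
class FluxSummary:
    """Interface fluxes around a production layer, human-facing orientation.

    upward_flux is positive toward the overlying water; downward_flux is
    positive into the deeper sample. Fractions are defined only when the
    total export is positive (status "ok"); a net-sink layer carries NaN
    fractions and status "net sink".
    """

    upward_flux_umol_m2_s: float
    downward_flux_umol_m2_s: float
    production_layer_mm: tuple[float, float]
    status: str = "ok"

    @property
    def total_export_umol_m2_s(self) -> float:
        return self.upward_flux_umol_m2_s + self.downward_flux_umol_m2_s

    @property
    def fraction_up(self) -> float:
        if self.total_export_umol_m2_s <= 0:
            return math.nan
        return self.upward_flux_umol_m2_s / self.total_export_umol_m2_s

    @property
    def fraction_down(self) -> float:
        if self.total_export_umol_m2_s <= 0:
            return math.nan
        return self.downward_flux_umol_m2_s / self.total_export_umol_m2_s


@dataclass
class PenetrationResult:
    depth_mm: float
    reached: bool
    multiple_crossings: bool = False


# ---------------------------------------------------------------------------
# I/O: '#'-prefixed "key: value" header, then two numeric columns.
# ---------------------------------------------------------------------------

_META_KEYS = {"quantity", "units", "temperature_c", "light"}


def load_profile(path: str | Path) -> DepthProfile:
    """Read a two-column (depth_mm, value) profile file with '#' metadata."""
    path = Path(path)
    meta: dict[str, str] = {}
    depths: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip().lower()] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                depths.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    order = np.argsort(depths)
    d = np.asarray(depths)[order]
    v = np.asarray(values)[order]
    if np.any(np.diff(d) == 0):
        dup = d[np.where(np.diff(d) == 0)[0][0]]
        raise ValueError(f"{path}: duplicate depth {dup} mm")
    temp = meta.get("temperature_c")
    return DepthProfile(
        d, v,
        quantity=meta.get("quantity", "O2"),
        units=meta.get("units", "uM"),
        temperature_C=float(temp) if temp is not None else None,
        light_label=meta.get("light", ""),
    )


def write_profile(profile: DepthProfile, path: str | Path) -> None:
    """Write a profile in the same format :func:`load_profile` reads."""
    buf = io.StringIO()
    buf.write(f"# quantity: {profile.quantity}\n")
    buf.write(f"# units: {profile.units}\n")
    if profile.temperature_C is not None:
        buf.write(f"# temperature_C: {profile.temperature_C}\n")
    if profile.light_label:
        buf.write(f"# light: {profile.light_label}\n")
    for d, v in zip(profile.depths_mm, profile.values):
        buf.write(f"{float(d):.17g} {float(v):.17g}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Derivative-based inversion
# ---------------------------------------------------------------------------

def _window_slice(profile: DepthProfile, center_mm: float, window_mm: float) -> np.ndarray:
    half = window_mm / 2.0
    mask = (profile.depths_mm >= center_mm - half) & (profile.depths_mm <= center_mm + half)
    return np.where(mask)[0]


def flux_at(
    profile: DepthProfile,
    D_eff: float,
    depth_mm: float,
    window_mm: float = 0.2,
    order: int = 1,
    eval_depth_mm: float | None = None,
) -> float:
    """Fickian flux J = -D_eff dc/dz at a depth, µmol m⁻² s⁻¹.

    A polynomial of degree ``order`` is least-squares fitted to all points
    within ``window_mm/2`` of ``depth_mm`` and differentiated at
    ``eval_depth_mm`` (default: the window center). ``order=1`` gives the
    plain gradient of an OLS line; ``order=2`` with an off-center evaluation
    depth recovers boundary gradients of curved profiles exactly when the
    profile is locally quadratic. Positive J is transport in the +z
    (downward) direction.
    """
    idx = _window_slice(profile, depth_mm, window_mm)
    if len(idx) < order + 2:
        raise ValueError(
            f"need >={order + 2} points within {window_mm / 2} mm of depth "
            f"{depth_mm} mm, got {len(idx)}"
        )
    z = profile.depths_mm[idx] * MM_TO_M
    c = profile.values[idx] * UM_TO_UMOL_M3
    if np.ptp(z) == 0:
        raise ValueError("zero depth variance in fit window")
    z_eval = (depth_mm if eval_depth_mm is None else eval_depth_mm) * MM_TO_M
    z0 = z.mean()  # center for conditioning
    coeffs = np.polyfit(z - z0, c, order)
    slope = float(np.polyval(np.polyder(coeffs), z_eval - z0))
    return -D_eff * slope


def interface_flux(
    profile: DepthProfile, D_eff: float, side: str = "top", window_mm: float = 0.2
) -> float:
    """Flux across the top or bottom end of the profile, µmol m⁻² s⁻¹."""
    if side == "top":
        center = profile.depths_mm[0] + window_mm / 2.0
    elif side == "bottom":
        center = profile.depths_mm[-1] - window_mm / 2.0
    else:
        raise ValueError("side must be 'top' or 'bottom'")
    return flux_at(profile, D_eff, center, window_mm)


def _uniform_grid(profile: DepthProfile, window_pts: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (z, c) on a uniform grid, resampling irregular grids.

    Spacing ratios above 3 within one window cannot be fixed by interpolation
    without inventing structure, so they raise.
    """
    z = profile.depths_mm
    dz = np.diff(z)
    ratio = dz.max() / dz.min()
    if np.allclose(dz, dz[0], rtol=1e-8):
        return z, profile.values
    # local check: spacing ratio within any window of window_pts points
    for i in range(len(dz) - window_pts + 2):
        w = dz[i : i + window_pts - 1]
        if w.max() / w.min() > 3.0:
            raise ValueError(
                "grid spacing varies more than 3-fold within a derivative window; "
                "resample the profile to a regular grid first"
            )
    step = float(np.median(dz))
    grid = np.arange(z[0], z[-1] + step / 2, step)
    interp = PchipInterpolator(z, profile.values)
    return grid, interp(grid)


def net_rate_profile(
    profile: DepthProfile, D_eff: float, window_pts: int = 5, poly_order: int = 2
) -> RateProfile:
    """Volumetric net rate -D_eff c''(z) per depth bin, mmol m⁻³ s⁻¹.

    The second derivative is estimated with a moving Savitzky-Golay window;
    the outermost half-windows fall back to one-sided fits and are flagged as
    lower-confidence edge bins.
    """
    if window_pts % 2 == 0 or window_pts < poly_order + 2:
        raise ValueError("window_pts must be odd and >= poly_order + 2")
    if len(profile) < window_pts:
        raise ValueError("profile shorter than derivative window")
    z, c = _uniform_grid(profile, window_pts)
    dz_m = (z[1] - z[0]) * MM_TO_M
    c_si = c * UM_TO_UMOL_M3
    d2 = savgol_filter(
        c_si, window_length=window_pts, polyorder=poly_order, deriv=2, delta=dz_m
    )
    rates_umol = -D_eff * d2  # µmol m⁻³ s⁻¹
    edge = np.zeros(len(z), dtype=bool)
    half = window_pts // 2
    edge[:half] = True
    edge[-half:] = True
    return RateProfile(
        bin_centers_mm=z,
        net_rate_mmol_m3_s=rates_umol / 1e3,
        window_pts=window_pts,
        poly_order=poly_order,
        edge_bin=edge,
    )


def production_layer(
    rates: RateProfile, threshold_fraction: float = 0.05
) -> tuple[float, float] | None:
    """Bounds of the maximal contiguous layer of positive net production.

    Bins with rate above ``threshold_fraction`` of the peak positive rate are
    grouped into runs; the longest run (ties: shallowest) is returned as a
    (top_mm, bottom_mm) interval extended by half a bin on each side. Returns
    None when no bin is positive.
    """
    r = rates.net_rate_mmol_m3_s
    if len(r) == 0 or r.max() <= 0:
        return None
    above = r > threshold_fraction * r.max()
    best: tuple[int, int] | None = None
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    assert best is not None
    z = rates.bin_centers_mm
    half = (z[1] - z[0]) / 2.0 if len(z) > 1 else 0.0
    return (float(z[best[0]] - half), float(z[best[1]] + half))


def _flux_in_interval(
    profile: DepthProfile, D: float, lo_mm: float, hi_mm: float,
    eval_mm: float, order: int = 2,
) -> float:
    """Fickian flux from a polynomial fit over [lo, hi], evaluated at eval_mm."""
    mask = (profile.depths_mm >= lo_mm - 1e-12) & (profile.depths_mm <= hi_mm + 1e-12)
    z = profile.depths_mm[mask] * MM_TO_M
    c = profile.values[mask] * UM_TO_UMOL_M3
    if len(z) < order + 2:
        raise ValueError(
            f"need >={order + 2} points in [{lo_mm}, {hi_mm}] mm, got {len(z)}"
        )
    z0 = z.mean()
    coeffs = np.polyfit(z - z0, c, order)
    slope = float(np.polyval(np.polyder(coeffs), eval_mm * MM_TO_M - z0))
    return -D * slope


def export_partition(
    profile: DepthProfile,
    D_eff: float,
    layer: tuple[float, float],
    window_mm: float = 0.4,
    D_water: float | None = None,
) -> FluxSummary:
    """O2 export fluxes across the boundaries of a production layer.

    The upward flux (toward the water) is the negated Fickian flux across the
    layer top; the downward flux is the Fickian flux across the layer bottom.
    Each is a quadratic fitted to the window just outside the layer and
    differentiated at the boundary itself, which is exact for the
    piecewise-quadratic profiles of steady-state diffusion with
    piecewise-constant rates. Fit windows never straddle the sample surface:
    when the layer starts at (or above) depth 0 the top gradient is fitted on
    the water side of the diffusive boundary layer with the molecular
    diffusivity ``D_water`` (required in that case). When the layer is a net
    source both fluxes are positive and their sum is the total export.
    """
    top, bottom = layer
    if top >= bottom:
        raise ValueError("layer top must be above (smaller than) layer bottom")
    if top < profile.depths_mm[0] or bottom > profile.depths_mm[-1]:
        raise ValueError("layer lies outside the profile depth span")
    if top > 0:
        j_top = _flux_in_interval(
            profile, D_eff, max(0.0, top - window_mm), top, eval_mm=top
        )
    else:
        if D_water is None:
            raise ValueError(
                "layer starts at the surface: the top gradient lies in the "
                "boundary layer, pass D_water (molecular diffusivity)"
            )
        j_top = _flux_in_interval(
            profile, D_water, top - window_mm, top, eval_mm=top
        )
    j_bottom = _flux_in_interval(
        profile, D_eff, bottom, min(bottom + window_mm, profile.depths_mm[-1]),
        eval_mm=bottom,
    )
    up = -j_top
    down = j_bottom
    status = "ok" if up + down > 0 else "net sink"
    return FluxSummary(up, down, (float(top), float(bottom)), status)


def penetration_depth(
    profile: DepthProfile, threshold: float = 0.0
) -> PenetrationResult:
    """Depth at which the signal first falls to ``threshold``, mm.

    The crossing is linearly interpolated between grid points. If the signal
    crosses more than once, the deepest crossing is returned and flagged. If
    the signal never reaches the threshold, the bottom depth is returned with
    ``reached=False``.
    """
    z = profile.depths_mm
    v = profile.values
    crossings: list[float] = []
    for i in range(len(v) - 1):
        if v[i] > threshold >= v[i + 1]:
            if v[i + 1] == threshold:
                crossings.append(float(z[i + 1]))
            else:
                frac = (v[i] - threshold) / (v[i] - v[i + 1])
                crossings.append(float(z[i] + frac * (z[i + 1] - z[i])))
    if v[0] <= threshold:
        crossings.insert(0, float(z[0]))
    if not crossings:
        return PenetrationResult(float(z[-1]), reached=False)
    return PenetrationResult(
        crossings[-1], reached=True, multiple_crossings=len(crossings) > 1
    )


def dark_areal_respiration(
    dark_profile: DepthProfile, D: float, window_mm: float = 0.2
) -> float:
    """Areal respiration from a dark profile, µmol m⁻² s⁻¹ (positive influx).

    Equal to the downward flux across the diffusive boundary layer, fitted on
    the water side (depths <= 0) with the molecular diffusivity ``D`` (φ = 1).
    Falls back to the topmost window if no water-side points are present.
    """
    water = dark_profile.depths_mm <= 0
    if water.sum() >= 3:
        center = float(dark_profile.depths_mm[water].mean())
        span = float(np.ptp(dark_profile.depths_mm[water])) + 1e-12
        j = flux_at(dark_profile, D, center, max(window_mm, span))
    else:
        j = interface_flux(dark_profile, D, side="top", window_mm=window_mm)
    return abs(j)


def transient_zone(
    profiles: Sequence[DepthProfile], window_mm: float = 2.0
) -> tuple[float, float] | None:
    """Depth interval of the strongest increase between first and last profile.

    Profiles (e.g., H2S raw signal at successive temperatures) are resampled
    to the common depth range; the smoothed last-minus-first difference is
    thresholded at 50% of its maximum and the contiguous interval around the
    maximum is returned. None if the profiles are identical.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    lo = max(p.depths_mm[0] for p in profiles)
    hi = min(p.depths_mm[-1] for p in profiles)
    if lo >= hi:
        raise ValueError("profiles have disjoint depth ranges")
    step = float(np.median(np.diff(profiles[0].depths_mm)))
    grid = np.arange(lo, hi + step / 2, step)
    first = PchipInterpolator(profiles[0].depths_mm, profiles[0].values)(grid)
    last = PchipInterpolator(profiles[-1].depths_mm, profiles[-1].values)(grid)
    diff = last - first
    n_smooth = max(1, int(round(window_mm / step)))
    kernel = np.ones(n_smooth) / n_smooth
    smoothed = np.convolve(diff, kernel, mode="same")
    peak = smoothed.max()
    if peak <= 0:
        return None
    above = smoothed > 0.5 * peak
    imax = int(np.argmax(smoothed))
    i = imax
    while i > 0 and above[i - 1]:
        i -= 1
    j = imax
    while j + 1 < len(above) and above[j + 1]:
        j += 1
    return (float(grid[i]), float(grid[j]))
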