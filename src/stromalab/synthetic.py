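"""Forward generators with known ground truth for every analysis stage.

The centrepiece is an exact steady-state solver for one-dimensional
diffusion with piecewise-constant volumetric net rates,

    D(z) c''(z) + R(z) = 0,

on a domain consisting of a diffusive boundary layer (molecular D, no
reaction) over a porous sample (D_eff = φD), with a fixed concentration at
the top of the boundary layer and zero flux at the bottom. Because R is
piecewise constant the flux J(z) = -D c' is piecewise linear and c is
piecewise quadratic, so the solution is closed-form and serves as an
independent oracle for the profile-inversion code. A finite-difference
solver over the same operator provides a second, numerically independent
route.

Scenario presets mirror the magnitudes of a high-altitude stromatolite:
a "fresh" sample with a sub-surface production layer (0.25-0.75 mm, net
photosynthesis ~4 mmol m⁻³ s⁻¹) sandwiched by respiration, a "modified"
(UV-relieved) sample with ~10-fold higher production concentrated in the
top 200 µm, and a "dark" respiration-only state.

The other generators produce exponentially attenuated spectral irradiance,
Gaussian-band reflectance cubes, Gaussian-peak chromatograms with exact
areas, multinomial OTU tables from long-tailed abundance models, and
sequencing reads with a planned per-read violation ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import physchem
from .diversity import _IUPAC, OTUTable, ReadRecord
from .light import SpectralProfile
from .microprofiles import MM_TO_M, UM_TO_UMOL_M3, DepthProfile
from .pigments import Chromatogram, HyperspectralCube

__all__ = [
    "RateScenario", "SteadyStateTruth", "PRESETS",
    "solve_steady_profile", "solve_steady_fd",
    "make_spectral_profiles", "make_hyperspectral_cube",
    "make_chromatogram", "make_otu_table", "make_reads",
]


# ---------------------------------------------------------------------------
# Reaction-diffusion profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateScenario:
    """A prescribed steady-state O2 budget.

    layers: (top_mm, bottom_mm, rate) with production positive and
    consumption negative, in mmol m⁻³ s⁻¹; layers must lie inside
    [0, depth_mm] and not overlap.
    """

    layers: tuple[tuple[float, float, float], ...]
    boundary_concentration_uM: float = 300.0
    dbl_thickness_mm: float = 0.3
    depth_mm: float = 5.0
    porosity: float = 0.5
    temperature_C: float = 25.0
    salinity_gL: float = 48.0
    noise_sigma_fraction: float = 0.0
    seed: int = 0
    light_label: str = ""

    def __post_init__(self) -> None:
        if self.noise_sigma_fraction < 0:
            raise ValueError("noise sigma must be >= 0")
        spans = sorted((t, b) for t, b, _ in self.layers)
        for (t, b) in spans:
            if not 0.0 <= t < b <= self.depth_mm:
                raise ValueError(f"layer ({t}, {b}) outside [0, {self.depth_mm}] mm")
        for (_, b1), (t2, _) in zip(spans, spans[1:]):
            if t2 < b1:
                raise ValueError("layers overlap")

    @property
    def D_water(self) -> float:
        return physchem.o2_diffusivity(self.temperature_C, self.salinity_gL)

    @property
    def D_eff(self) -> float:
        return physchem.effective_diffusivity(self.D_water, self.porosity)


#: Presets matching the magnitudes measured in the field study conditions:
#: production rates, layer bounds and the respiration partition are chosen so
#: that the "fresh" layer exports ~2 µmol m⁻² s⁻¹ split ~45/55 up/down, the
#: "modified" layer ~10 µmol m⁻² s⁻¹ split 70/30, and the "dark" state takes
#: up ~0.28 µmol m⁻² s⁻¹.
PRESETS: dict[str, RateScenario] = {
    "fresh": RateScenario(
        layers=((0.0, 0.25, -0.9), (0.25, 0.75, 4.0), (0.75, 1.85, -1.0)),
        boundary_concentration_uM=380.0,
        light_label="600 umol photons m-2 s-1",
    ),
    "modified": RateScenario(
        layers=((0.0, 0.2, 50.0), (0.2, 0.575, -8.0)),
        boundary_concentration_uM=200.0,
        light_label="600 umol photons m-2 s-1",
    ),
    "dark": RateScenario(
        layers=((0.0, 0.8, -0.35),),
        boundary_concentration_uM=160.0,
        light_label="dark",
    ),
}


@dataclass
class SteadyStateTruth:
    """Ground truth accompanying a simulated profile (noise-free solution)."""

    scenario: RateScenario
    #: Fickian flux at the sample surface (positive downward), µmol m⁻² s⁻¹.
    surface_flux_umol_m2_s: float
    #: bounds of the positive-rate (production) layer, or None.
    production_layer_mm: tuple[float, float] | None
    upward_flux_umol_m2_s: float
    downward_flux_umol_m2_s: float
    #: depth-integrated consumption magnitude, µmol m⁻² s⁻¹.
    areal_respiration_umol_m2_s: float
    #: noise-free concentration on the output grid, µM.
    clean_values_uM: np.ndarray
    depths_mm: np.ndarray

    @property
    def total_export_umol_m2_s(self) -> float:
        return self.upward_flux_umol_m2_s + self.downward_flux_umol_m2_s


def _segments(scn: RateScenario) -> list[tuple[float, float, float, float]]:
    """(z0_m, z1_m, R_umol_m3_s, D) segments from -DBL to the bottom."""
    breaks = {0.0, scn.depth_mm}
    for t, b, _ in scn.layers:
        breaks.update((t, b))
    edges = sorted(breaks)
    segs = [(-scn.dbl_thickness_mm * MM_TO_M, 0.0, 0.0, scn.D_water)]
    for z0, z1 in zip(edges, edges[1:]):
        rate = 0.0
        for t, b, r in scn.layers:
            if t <= z0 and z1 <= b:
                rate = r * 1e3  # mmol -> µmol m⁻³ s⁻¹
        segs.append((z0 * MM_TO_M, z1 * MM_TO_M, rate, scn.D_eff))
    return segs


def _suffix_integral(segs: list[tuple[float, float, float, float]]) -> list[float]:
    """G(z0_k) = ∫_{z0_k}^{L} R ds for each segment start, µmol m⁻² s⁻¹."""
    g = 0.0
    out = [0.0] * len(segs)
    for k in range(len(segs) - 1, -1, -1):
        z0, z1, r, _ = segs[k]
        g += r * (z1 - z0)
        out[k] = g
    return out


def _evaluate(scn: RateScenario, z_m: np.ndarray) -> np.ndarray:
    """Closed-form concentration (µmol m⁻³) at depths z_m (m)."""
    segs = _segments(scn)
    G0 = _suffix_integral(segs)
    c_top = scn.boundary_concentration_uM * UM_TO_UMOL_M3
    # concentration at each segment start, marching down: c' = G/D
    c_starts = [c_top]
    for (z0, z1, r, D), g0 in zip(segs, G0):
        dz = z1 - z0
        c_starts.append(c_starts[-1] + (g0 * dz - r * dz**2 / 2.0) / D)
    c = np.empty_like(z_m)
    for i, z in enumerate(z_m):
        k = 0
        while k < len(segs) - 1 and z > segs[k][1] + 1e-15:
            k += 1
        z0, _, r, D = segs[k]
        dz = z - z0
        c[i] = c_starts[k] + (G0[k] * dz - r * dz**2 / 2.0) / D
    return c


def solve_steady_profile(
    scenario: RateScenario, grid_mm: float = 0.05
) -> tuple[DepthProfile, SteadyStateTruth]:
    """Exact steady-state profile for a scenario, with ground truth.

    Gaussian noise (``noise_sigma_fraction`` × boundary concentration) is
    added after solving; values are clipped at 0 so the profile remains a
    valid O2 series. Raises if the noise-free solution goes negative (the
    prescribed respiration exceeds the available O2).
    """
    z_mm = np.arange(-scenario.dbl_thickness_mm, scenario.depth_mm + grid_mm / 2, grid_mm)
    c = _evaluate(scenario, z_mm * MM_TO_M)
    if c.min() < 0:
        z_bad = z_mm[int(np.argmax(c < 0))]
        raise ValueError(
            f"anoxic below depth {z_bad:.2f} mm; shrink rates or domain"
        )
    segs = _segments(scenario)
    G0 = _suffix_integral(segs)
    production = [(t, b, r) for t, b, r in scenario.layers if r > 0]

    def G(z_mm_pt: float) -> float:
        z = z_mm_pt * MM_TO_M
        k = 0
        while k < len(segs) - 1 and z > segs[k][1] + 1e-15:
            k += 1
        z0, _, r, _ = segs[k]
        return G0[k] - r * (z - z0)

    if production:
        top = min(t for t, _, _ in production)
        bot = max(b for _, b, _ in production)
        layer: tuple[float, float] | None = (top, bot)
        up = G(top)  # c' = G/D; positive G above the source means upward escape
        down = -G(bot)
    else:
        layer, up, down = None, 0.0, 0.0
    resp = sum(-r * 1e3 * (b - t) * MM_TO_M for t, b, r in scenario.layers if r < 0)
    rng = np.random.default_rng(scenario.seed)
    values = c / UM_TO_UMOL_M3
    clean = values.copy()
    if scenario.noise_sigma_fraction > 0:
        values = values + rng.normal(
            0.0, scenario.noise_sigma_fraction * scenario.boundary_concentration_uM,
            size=values.shape,
        )
        values = np.clip(values, 0.0, None)
    profile = DepthProfile(
        z_mm, values, quantity="O2", units="uM",
        temperature_C=scenario.temperature_C, light_label=scenario.light_label,
    )
    truth = SteadyStateTruth(
        scenario=scenario,
        surface_flux_umol_m2_s=-G(0.0),
        production_layer_mm=layer,
        upward_flux_umol_m2_s=up,
        downward_flux_umol_m2_s=down,
        areal_respiration_umol_m2_s=resp,
        clean_values_uM=clean,
        depths_mm=z_mm,
    )
    return profile, truth


def solve_steady_fd(scenario: RateScenario, grid_mm: float = 0.01) -> DepthProfile:
    """Independent finite-difference solution of the same boundary problem.

    Conservative tridiagonal discretization of (D c')' = -R with a Dirichlet
    top and zero-flux bottom; used to cross-check the analytic solver.
    """
    from scipy.linalg import solve_banded

    z_mm = np.arange(-scenario.dbl_thickness_mm, scenario.depth_mm + grid_mm / 2, grid_mm)
    z = z_mm * MM_TO_M
    n = len(z)
    h = z[1] - z[0]
    segs = _segments(scenario)

    def rate_integral(lo: float, hi: float) -> float:
        """∫ R dz over [lo, hi], exact over the piecewise-constant segments."""
        total = 0.0
        for z0, z1, r, _ in segs:
            overlap = min(hi, z1) - max(lo, z0)
            if overlap > 0:
                total += r * overlap
        return total

    def D_at(zp: float) -> float:
        for z0, z1, _, d in segs:
            if z0 - 1e-15 <= zp <= z1 + 1e-15:
                return d
        return segs[-1][3]

    # finite-volume: faces halfway between nodes; exact cell-averaged rates
    D_face = np.array([D_at((z[i] + z[i + 1]) / 2.0) for i in range(n - 1)])
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    ab[1, 0] = 1.0
    rhs[0] = scenario.boundary_concentration_uM * UM_TO_UMOL_M3
    for i in range(1, n - 1):
        ab[0, i + 1] = D_face[i] / h          # upper diag
        ab[1, i] = -(D_face[i - 1] + D_face[i]) / h
        ab[2, i - 1] = D_face[i - 1] / h      # lower diag
        rhs[i] = -rate_integral(z[i] - h / 2, z[i] + h / 2)
    # bottom half-cell with zero flux through the lower face
    ab[1, n - 1] = -D_face[n - 2] / h
    ab[2, n - 2] = D_face[n - 2] / h
    rhs[n - 1] = -rate_integral(z[n - 1] - h / 2, z[n - 1])
    c = solve_banded((1, 1), ab, rhs)
    return DepthProfile(
        z_mm, np.clip(c / UM_TO_UMOL_M3, 0.0, None),
        quantity="O2", units="uM", temperature_C=scenario.temperature_C,
        light_label=scenario.light_label,
    )


# ---------------------------------------------------------------------------
# Light, cubes, chromatograms
# ---------------------------------------------------------------------------

def make_spectral_profiles(
    K_per_mm: dict[float, float],
    depths_mm: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SpectralProfile:
    """Exponentially attenuated normalized irradiance E_s = exp(-K z).

    Multiplicative Gaussian noise of relative magnitude ``noise_sigma`` is
    applied below the surface; the surface row stays exactly 1.
    """
    if depths_mm is None:
        depths_mm = np.arange(0.0, 1.55, 0.05)
    rng = np.random.default_rng(seed)
    wavelengths = np.array(sorted(K_per_mm))
    z = np.asarray(depths_mm, dtype=float)
    e = np.exp(-np.outer(z, np.array([K_per_mm[w] for w in wavelengths])))
    if noise_sigma > 0:
        factor = 1.0 + rng.normal(0.0, noise_sigma, size=e.shape)
        factor[z == 0, :] = 1.0
        e = np.clip(e * factor, 1e-12, None)
    return SpectralProfile(z, wavelengths, e)


def make_hyperspectral_cube(
    pigment_map: np.ndarray,
    band_center_nm: float = 676.0,
    band_width_nm: float = 15.0,
    band_strength: float = 1.0,
    baseline_reflectance: float = 0.6,
    wavelengths_nm: np.ndarray | None = None,
    surface_index: np.ndarray | None = None,
) -> HyperspectralCube:
    """Reflectance cube with a Gaussian pigment absorption band.

    R(x, z, λ) = baseline · exp(-strength · pigment(x, z) · g(λ)) with a
    normalized Gaussian band g centred at ``band_center_nm``; the region
    around 750 nm is left flat, so log10(R750/R676) is proportional to the
    pigment map (slope strength·log10 e at the band centre).
    """
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(400.0, 801.0, 2.0)
    pigment_map = np.asarray(pigment_map, dtype=float)
    if np.any(pigment_map < 0):
        raise ValueError("pigment map must be non-negative")
    n_x, n_z = pigment_map.shape
    g = np.exp(-0.5 * ((wavelengths_nm - band_center_nm) / band_width_nm) ** 2)
    absorb = band_strength * pigment_map[:, :, None] * g[None, None, :]
    reflectance = baseline_reflectance * np.exp(-absorb)
    return HyperspectralCube(
        np.arange(n_x, dtype=float),
        np.arange(n_z, dtype=float),
        wavelengths_nm,
        reflectance,
        surface_index=surface_index,
    )


def make_chromatogram(
    peaks: list[tuple[float, float, float]],
    t_span_min: tuple[float, float] = (0.0, 30.0),
    dt_min: float = 0.01,
    baseline_drift_AU_per_min: float = 0.0,
    noise_sigma_AU: float = 0.0,
    seed: int = 0,
) -> tuple[Chromatogram, list[float]]:
    """Sum of Gaussian elution peaks (center_min, sigma_min, area_AU_min).

    Returns the trace and the exact analytic areas (the ground truth).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t_span_min[0], t_span_min[1] + dt_min / 2, dt_min)
    a = baseline_drift_AU_per_min * (t - t[0])
    for center, sigma, area in peaks:
        if sigma <= 0:
            raise ValueError("peak width must be > 0")
        a = a + area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - center) / sigma) ** 2
        )
    if noise_sigma_AU > 0:
        a = a + rng.normal(0.0, noise_sigma_AU, size=a.shape)
    return Chromatogram(t, a), [area for _, _, area in peaks]


# ---------------------------------------------------------------------------
# OTU tables and reads
# ---------------------------------------------------------------------------

def _abundance_proportions(S: int, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "log-series":
        theta = 0.97
        ranks = np.arange(1, S + 1)
        w = theta**ranks / ranks
    elif model == "lognormal":
        w = np.exp(rng.normal(0.0, 1.2, size=S))
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    return w / w.sum()


def make_otu_table(
    n_samples: int = 2,
    S: int = 100,
    abundance_model: str = "log-series",
    depth: int | None = None,
    n_phyla: int = 8,
    seed: int = 0,
) -> tuple[OTUTable, np.ndarray]:
    """Multinomial OTU counts from a long-tailed abundance distribution.

    Every sample is drawn from the same true proportions (true richness S),
    so between-sample differences are pure sampling noise. Returns the table
    and the true proportions. Default depth is 100·S reads per sample.
    """
    if S < 1 or (depth is not None and depth < 1):
        raise ValueError("S and depth must be >= 1")
    rng = np.random.default_rng(seed)
    if depth is None:
        depth = 100 * S
    p = _abundance_proportions(S, abundance_model, rng)
    otus = [f"OTU{i:04d}" for i in range(S)]
    counts = pd.DataFrame(
        {f"S{j + 1}": rng.multinomial(depth, p) for j in range(n_samples)},
        index=otus,
    )
    phylum = pd.Series(
        [f"Phylum{(i % n_phyla) + 1:02d}" for i in range(S)], index=otus
    )
    return OTUTable(counts, phylum=phylum, similarity=0.97), p


_PRIMER_515F = "GTGCCAGCMGCCGCGGTAA"
_BASES = "ACGT"


def _random_sequence(length: int, rng: np.random.Generator, max_run: int = 4) -> str:
    """Random A/C/G/T sequence with homopolymer runs capped at ``max_run``."""
    seq = []
    run = 0
    prev = None
    for _ in range(length):
        choices = _BASES if run < max_run else _BASES.replace(prev, "")
        b = choices[rng.integers(len(choices))]
        run = run + 1 if b == prev else 1
        prev = b
        seq.append(b)
    return "".join(seq)


_VIOLATIONS = {"quality", "homopolymer", "primer", "length_short", "length_long"}


def make_reads(
    n: int,
    violation_plan: dict[int, set[str]] | None = None,
    primer: str = _PRIMER_515F,
    read_length: int = 250,
    seed: int = 0,
) -> tuple[list[ReadRecord], dict[int, set[str]]]:
    """Reads engineered to pass or fail exactly the planned filter criteria.

    ``violation_plan`` maps read index -> subset of {"quality",
    "homopolymer", "primer", "length_short", "length_long"}; unlisted reads
    pass every criterion. The plan is returned as the ground truth ledger.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    plan = {i: set(v) for i, v in (violation_plan or {}).items()}
    for i, v in plan.items():
        unknown = v - _VIOLATIONS
        if unknown:
            raise ValueError(f"unknown violations {unknown} for read {i}")
        if {"length_short", "length_long"} <= v:
            raise ValueError(f"read {i}: contradictory length plan")
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n):
        v = plan.get(i, set())
        length = read_length
        if "length_short" in v:
            length = 150
        if "length_long" in v:
            length = 1100
        body = _random_sequence(length - len(primer), rng)
        head = "".join(sorted(_IUPAC[p])[0] for p in primer)  # resolve ambiguity
        if "primer" in v:
            # flip the first primer position that is not fully ambiguous
            pos, disallowed = next(
                (k, sorted(set(_BASES) - _IUPAC[p])[0])
                for k, p in enumerate(primer)
                if _IUPAC[p] != set(_BASES)
            )
            head = head[:pos] + disallowed + head[pos + 1:]
        seq = head + body
        if "homopolymer" in v:
            pos = int(rng.integers(len(primer) + 5, len(seq) - 10))
            seq = seq[:pos] + "A" * 8 + seq[pos + 8:]
        mean_q = 20 if "quality" in v else 35
        quals = list(
            np.clip(rng.normal(mean_q, 2.0, size=len(seq)).round().astype(int), 2, 40)
        )
        # pin the realized mean on the right side of the threshold
        while (np.mean(quals) < 25) != ("quality" in v):
            quals[int(rng.integers(len(quals)))] += 1 if "quality" not in v else -1
        reads.append(ReadRecord(f"read_{i:05d}", seq, [int(q) for q in quals]))
    return reads, plan
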