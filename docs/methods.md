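# Methods

This note documents the models behind each module, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real field data.

## Physical corrections (`physchem`)

**Barometric pressure factor.** The 100%-air-saturation O2 reference at
altitude is the sea-level solubility scaled by the ratio of ambient to
sea-level pressure. The default model is the isothermal exponential
`PF = exp(-z/H)` with scale height `H = 8434 m`, which reproduces the
conventional two-decimal values 0.66 at 3500 m and 0.95 at 460 m. The
International Standard Atmosphere polynomial is available as an alternative
(`model="isa"`); it yields 0.65 at 3500 m, so it is not the default. No
humidity or temperature-profile refinements are applied.

**Salinity from conductivity.** Brine salinity is estimated from
conductivity assuming seawater ionic composition, via the PSS-78 polynomial
on the conductivity ratio `R = C/C(35,15,0)` with `C(35,15,0) =
42.914 mS cm⁻¹`. Above the nominal validity limit S = 42 the polynomial is
extrapolated as-is; for the waters of interest (S ≈ 48 at 70 mS cm⁻¹ and
25 °C) the extrapolation is mild. Practical salinity is treated
interchangeably with g L⁻¹, as is conventional in this context.

**O2 solubility.** The Garcia & Gordon combined fit (Benson & Krause data)
gives air-equilibrium O2 in µmol kg⁻¹; conversion to µM uses the EOS-80
one-atmosphere seawater density at (T, S). A fixed 1.0 kg L⁻¹ fallback
(`density_model="unit"`) shifts results by ~3% at S ≈ 48. The freshwater
check value at 25 °C (≈258 µM) validates the implementation to <2%. The fit
is extrapolated in the same spirit as PSS-78 for hypersaline waters; this
is the dominant systematic uncertainty in the percent-saturation numbers
and is why the saturation checks carry a ±3% tolerance.

**O2 diffusivity.** A built-in 0–40 °C table of the molecular diffusion
coefficient of O2 in water (1.10–2.89 × 10⁻⁹ m² s⁻¹) with linear
interpolation, multiplied by the linear salting-out correction
`1 − 0.00075·S`. Inside the porous sample the effective diffusivity is
`D_eff = φ·D` with porosity φ (default 0.5 for the bulk stromatolite
fabric); no separate tortuosity factor is applied beyond φ.

**PAR conversion.** Energy-to-quanta conversion for the solar PAR band uses
4.6 µmol photons per joule (130 W m⁻² ↔ ≈600 µmol photons m⁻² s⁻¹); the
factor is configurable since it is spectrum-dependent.

## Profile inversion (`microprofiles`)

Depth z increases downward, with 0 at the sample surface and negative
depths in the overlying water. Profiles are stored in mm and µM; all
physics is computed in SI. Reported fluxes use a human-facing orientation
(upward = toward the water, downward = into the sample); the raw Fickian
sign (positive = +z transport) is used internally.

**Derivatives.** Volumetric net rates come from a moving Savitzky–Golay
second derivative (default window 5 points, polynomial order 2). The
outermost half-windows are computed from one-sided fits and flagged
`edge_bin` (lower confidence). Irregular grids are resampled to the median
spacing with monotone (PCHIP) interpolation before differentiation; grids
whose spacing varies more than 3-fold within one window are rejected rather
than silently smoothed.

**Boundary fluxes.** Interface fluxes fit a straight line in a window
(default 0.2 mm). The export partition across a production layer instead
fits a *quadratic* to the window just outside each layer boundary and
differentiates it *at the boundary*. For steady-state diffusion with
piecewise-constant rates the concentration is piecewise quadratic, so this
estimator is exact on noise-free profiles, whereas a centered linear fit is
biased by the curvature (≈10% on thin-layer geometries). The partition
window default is 0.4 mm: wide enough to average sensor noise, narrow
enough to stay within the homogeneous zones adjacent to the layers in the
scenarios of interest. Fit windows never straddle the sample surface; when
a production layer reaches the surface the upper gradient is fitted on the
water side of the diffusive boundary layer with the molecular diffusivity
(φ = 1), mirroring the physical split between the DBL and the porous
matrix.

**Production layer.** The maximal contiguous run of bins with net rate
above 5% of the peak positive rate, returned with half-bin extension on
each side. The 5% threshold suppresses single-bin noise layers;
it is configurable. Because the Savitzky–Golay response smears rate
discontinuities over half a window, recovered bounds jitter by about one
bin under realistic noise; the replicate mean is unbiased to within half a
bin.

**Penetration depth** interpolates the first (deepest, if multiple,
flagged) down-crossing of a threshold (default 0: the detection limit).
**Dark areal respiration** is the downward flux across the DBL fitted
strictly on the water side. **Transient zones** (e.g., H2S build-up across
a temperature series) threshold the smoothed last-minus-first difference at
50% of its maximum and report the contiguous interval around the peak.

## Light attenuation (`light`)

Attenuation coefficients are least-squares slopes of ln E_s against depth —
exact on noise-free exponentials. The UV extrapolation decomposes the
measured pair K(676), K(750) into power-law scattering
`K_s(λ) = K750·(750/λ)ⁿ` and residual pigment absorption at 676 nm, then
brackets the unknown UV absorption of cellular/detrital material as
`[0.5, 2.0] × K_abs(676)`, evaluated at 10 nm steps over 280–400 nm. With
the default `n = 1` the worked field inputs (100-fold at 676 nm, 3-fold at
750 nm over 1 mm) give an interval that brackets the 140–2500-fold per mm
field estimate. All four knobs (n, bounds, band, step) are exposed and
echoed in CLI output; the interval should be read as an order-of-magnitude
bracket, not a measurement.

## Pigments (`pigments`)

Peak areas are trapezoidal integrals above a straight baseline drawn
between the window endpoints (configurable to a zero baseline); negative
areas clamp to 0. Pigment mass follows `m = F·A/(e_m·d)` with the built-in
extinction coefficients (L g⁻¹ cm⁻¹): Chl a 79.95, BChl a 60, BChl c 86;
the unit chain (ml → L) makes 1 AU·min at F = 0.5 ml min⁻¹ and e = 79.95
equal 6.25 µg. Phycocyanin uses the standard two-wavelength cyanobacterial
equation `PC = (A615 − 0.474·A652)/5.34` (mg ml⁻¹ of extract), scaled by
extract volume and dry weight. The hyperspectral Chl a index is
`log10(R750/R676)` — base 10 by convention here; a different base only
rescales the relative index. Non-positive reflectance pixels and pixels
above the surface line are masked, never propagated. Missing top-layer
concentrations are an explicit imputation step, never silent.

## Diversity (`diversity`)

Read filtering keeps a read iff mean Phred quality ≥ 25, longest
homopolymer ≤ 6, primer mismatches (5′ end, IUPAC-aware) = 0, and length in
[200, 1000] bp; rejection counts attribute a read to every criterion it
fails. OTU clustering itself is an external step — tables at a stated
similarity level are inputs.

The comparison procedure removes OTUs with ≤2 total reads (singletons and
doubletons), subsamples every sample to a common depth (default 1557, the
smallest dataset in the original comparison) in 10 replicates *without*
replacement (hypergeometric; a with-replacement mode exists for sensitivity
checks), averages alpha metrics over replicates, and computes Bray-Curtis
on phylum-level relative abundances feeding a UPGMA tree. Shannon uses the
natural log (the comparison is internal; switchable); equitability of a
single-OTU sample is defined as 0 to avoid 0/0; Chao1 uses the classic
`S + F1²/(2F2)` with the bias-corrected `S + F1(F1−1)/2` when F2 = 0.
Rarefaction offers the exact hypergeometric expectation (preferred for
tests) alongside Monte-Carlo. UPGMA heights come from average-linkage
agglomeration with leaves at half the merge height (ultrametric by
construction); samples are sorted lexicographically first so ties break
deterministically.

## Synthetic data (`synthetic`)

**Steady-state profiles.** The solver integrates `D(z)c'' + R(z) = 0`
exactly: with piecewise-constant R the flux is piecewise linear and c
piecewise quadratic, so the solution is closed-form. The domain is a
diffusive boundary layer (default 300 µm, molecular D, no reaction) with a
fixed concentration at its top, over a porous sample (default 5 mm, D_eff)
with zero flux at the bottom. An independent conservative finite-volume
solver cross-checks the analytic solution (<0.1% of the boundary
concentration on a 10 µm grid). Scenarios whose noise-free solution goes
negative are rejected with the first anoxic depth reported. Noise is
additive i.i.d. Gaussian (microsensor noise is approximately
signal-independent at these scales), applied after solving, with values
clipped at 0.

The presets encode the magnitudes of the field system: `fresh` prescribes
net photosynthesis +4.0 mmol m⁻³ s⁻¹ at 0.25–0.75 mm between respiration
zones (−0.9 above, −1.0 at 0.75–1.85 mm), yielding 2.0 µmol m⁻² s⁻¹ total
export split 45/55 up/down; `modified` prescribes +50 mmol m⁻³ s⁻¹ in the
top 200 µm over −8 mmol m⁻³ s⁻¹, yielding 10 µmol m⁻² s⁻¹ split 70/30;
`dark` prescribes −0.35 mmol m⁻³ s⁻¹ over the top 0.8 mm (0.28
µmol m⁻² s⁻¹ influx). Boundary concentrations (380/200/160 µM) were set
once so the noise-free solutions stay positive with a small oxic tail;
these are supersaturated values consistent with a highly productive
environment.

**Other generators.** Spectral profiles are exact exponentials with
optional multiplicative noise; reflectance cubes apply a Gaussian 676 nm
absorption band to a flat baseline (leaving 750 nm clean), so the Chl index
is analytically proportional to the pigment map; chromatograms are Gaussian
peaks with exact analytic areas plus optional drift/noise; OTU tables are
multinomial draws from a log-series (`p_i ∝ θ^i/i`, θ = 0.97, chosen so a
depth of 100·S observes ≈all of S while keeping a long tail) or lognormal
abundance model; reads are constructed to pass or fail exactly a planned
set of filter criteria, with the plan returned as ground truth. All
generators are seed-deterministic.

**What the tests show.** Recovery tests demonstrate that the inversion is
unbiased and precise *under the model that generated the data*: 1-D steady
state, piecewise-constant rates, homogeneous porosity, Gaussian noise. Real
profiles add lateral heterogeneity, advection in the DBL, sensor drift and
calibration error, none of which the generator emulates; the recovery rates
quoted in the tests (e.g., export flux within 10% in ≥95% of 1%-noise
replicates) are therefore upper bounds on real-data performance, not field
error bars.

## Problem sizes and defaults in the validation suite

The noisy-recovery checks use 200 seeded replicates per preset on a 50 µm
grid (≈107 points per profile); Chao1 recovery uses 50 seeded tables of
true richness 100 at depth 10⁴; rarefaction cross-validation uses 1000
Monte-Carlo subsamples. These sizes give Monte-Carlo standard errors well
below the tolerances being asserted while keeping the suite fast.

## Known limitations

* Solubility and salinity polynomials are extrapolated beyond their
  calibrated ranges for hypersaline brines; errors of a few percent are
  expected and absorbed in the stated tolerances.
* The UV attenuation bracket inherits its absorption bounds by calibration,
  not by independent measurement.
* H2S is handled as an uncalibrated raw signal; no speciation or pH-buffer
  chemistry is attempted.
* No transient (time-dependent) diffusion inversion; the transient-zone
  operator compares steady snapshots only.
* The diversity chain starts at OTU tables; clustering, taxonomy assignment
  and chimera checking are out of scope.
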