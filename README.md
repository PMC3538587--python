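# stromalab

Quantitative analysis tools for benthic phototrophic ecosystems studied with
microsensors — high-altitude stromatolites, hypersaline microbial mats and
similar systems — together with the amplicon-diversity comparison chain used
to place their communities in context.

The package covers four measurement modalities and the synthetic-data
generators needed to validate each of them offline:

* **`physchem`** — physical corrections for O2 microsensor calibration at
  altitude: the barometric pressure factor PF, practical salinity from
  conductivity (PSS-78, extrapolated for brines), Garcia & Gordon O2
  solubility, percent air saturation (`PF × C_sat(T, S)` as the 100%
  reference), O2 diffusivity with porosity correction (`D_eff = φ·D`), and
  PAR energy-to-photon conversion.
* **`microprofiles`** — inversion of steady-state O2 depth profiles by
  Fick's law: interface fluxes from the local gradient (`J = -D_eff dc/dz`),
  volumetric net photosynthesis from the curvature
  (`net PS = -D_eff d²c/dz²`, Savitzky–Golay windows), production-layer
  bounds, the up/down export partition across the layer, O2 penetration
  depth, dark areal respiration, and the depth zone of strongest change in a
  temperature series of (e.g. H2S) profiles.
* **`light`** — diffuse attenuation coefficients of normalized scalar
  irradiance, and a bounded extrapolation of UV attenuation from the
  676 nm / 750 nm pair (scattering `K750·(750/λ)ⁿ` plus pigment absorption
  bracketed as a multiplier range of the 676 nm residual).
* **`pigments`** — HPLC peak integration and pigment mass
  `m = F·A/(e_m·d)`, spectrophotometric phycocyanin, the hyperspectral
  Chl a index `log10(R750/R676)`, and pigment depth-profile correlation.
* **`diversity`** — pyrosequencing read filtering (mean quality,
  homopolymer runs, primer mismatches, length), rare-OTU removal,
  fixed-depth replicate subsampling, alpha metrics (observed OTUs, Shannon,
  equitability, Chao1), analytic and Monte-Carlo rarefaction, phylum-level
  Bray-Curtis and UPGMA clustering.
* **`synthetic`** — exact piecewise-quadratic solutions of steady-state
  diffusion–reaction profiles (with a finite-difference cross-check),
  attenuated spectra, reflectance cubes, Gaussian-peak chromatograms,
  multinomial OTU tables and reads with planned filter violations — all with
  ground truth returned alongside.

## Worked example

```python
from stromalab import physchem as pc, microprofiles as mp, synthetic as syn

# --- sensor calibration context at 3500 m altitude --------------------
pf = pc.pressure_factor(3500)
sal = pc.salinity_from_conductivity(70.0, 25.0)   # lake conductivity, mS/cm
env = pc.EnvContext(temperature_C=25.0, salinity_gL=sal, pressure_factor=pf)
print(f"pressure factor (3500 m):      {pf:.3f}")
print(f"salinity from 70 mS/cm:        {sal:.1f} g/L")
print(f"air-saturation reference:      {pc.air_saturation_reference(env):.1f} uM")
print(f"650 uM as % air saturation:    {pc.percent_air_saturation(650.0, env):.0f}%")

# --- invert a simulated steady-state O2 profile -----------------------
scn = syn.PRESETS["fresh"]
profile, truth = syn.solve_steady_profile(scn)
rates = mp.net_rate_profile(profile, scn.D_eff)
layer = mp.production_layer(rates)
summary = mp.export_partition(profile, scn.D_eff, layer, D_water=scn.D_water)
print(f"production layer:              {layer[0]:.2f}-{layer[1]:.2f} mm")
print(f"total O2 export:               {summary.total_export_umol_m2_s:.2f} umol/m2/s")
print(f"partition up/down:             {summary.fraction_up:.2f}/{summary.fraction_down:.2f}")
```

prints

```
pressure factor (3500 m):      0.660
salinity from 70 mS/cm:        47.9 g/L
air-saturation reference:      129.8 uM
650 uM as % air saturation:    501%
production layer:              0.22-0.77 mm
total O2 export:               1.95 umol/m2/s
partition up/down:             0.45/0.55
```

The pressure factor at 3500 m reduces the air-equilibrium O2 reference to
about 130 µM, so a measured peak of 650 µM corresponds to roughly five-fold
supersaturation. The simulated "fresh" sample prescribes a photosynthetic
layer at 0.25–0.75 mm exporting 2 µmol O2 m⁻² s⁻¹ with a 45/55 up/down
split; the inversion recovers the layer to within one depth bin and the
partition almost exactly.

A command-line interface mirrors the library
(`stromalab physchem|profiles|light|pigments|diversity|simulate ...`); every
subcommand emits one JSON record with inputs, model choices and results.

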