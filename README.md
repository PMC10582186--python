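# mehgrid

Dietary methylmercury (MeHg) exposure inventories on a 1 km grid.

Dietary intake — above all of rice and fish — is the dominant route of human
MeHg exposure, and chronic low-dose exposure carries cardiovascular,
neurological and developmental risks. Health-risk assessment needs exposure
maps at the resolution where people actually live, but consumption
statistics stop at the city or county level. `mehgrid` implements the
standard two-stage construction used for high-resolution exposure datasets
of urban agglomerations: build a county-level estimated-daily-intake (EDI)
inventory from food MeHg concentrations and per-capita consumption, then
downscale it to grid cells with a calibrated population / food-expenditure
proxy, with Monte Carlo percentile bounds for the uncertainty.

It is aimed at exposure modellers and environmental-health researchers who
have (or want to emulate) yearbook-style consumption tables, literature
concentration compilations and a LandScan-like population raster.

## The model

**Inventory.** For food *i* and city *j*, per-capita intake is derived from
per-capita consumption via a national intake/consumption ratio, and the
city urban/rural EDIs divide the concentration-weighted intake by adult
body weight:

```
I_ij  = CON_ij · NI_i / NCON_i            (g d⁻¹ capita⁻¹)
EDI_j = Σ_i (I_ij · C_i) / BW             (μg kg⁻¹ d⁻¹)
EDI_n = UEDI_j · r_n + REDI_j · (1 − r_n)
```

where `C_i` is the MeHg concentration of food *i* (μg kg⁻¹), `BW` the mean
adult body weight (61.75 kg, the average of 66.2 kg male and 57.3 kg
female means) and `r_n` the urbanization rate of county *n* in city *j*.

Sparse annual concentration series are completed by duplicate averaging,
linear interpolation inside gaps (a 4-year gap fills with weights
0.25/0.5/0.75) and constant-rate edge extrapolation. Yearbook consumption
tables are patched before use: aggregated categories (e.g. a single "fish"
row) are split by expenditure/price or production shares, and cities
without tables are filled from cities of similar per-capita GDP or from an
explicit level-city/structure-city pairing.

**Gridding.** The gridded population `g_ni` (nulls set to zero inside
counties) is calibrated so county sums match official totals, converted to
a food-expenditure proxy, and the county EDI is allocated by proxy share:

```
p_ni   = g_ni · pop_n / Σ_i g_ni
CON_ni = p_ni · pCON_n
EDI_ni = EDI_n · CON_ni / Σ_i CON_ni
```

Every step is mass-conserving per county, which the test suite checks to
1e-9 relative error.

**Uncertainty.** Each Monte Carlo draw (default 10,000) perturbs
concentrations, intakes and body weight and recomputes the inventory; the
empirical 10th/90th percentiles (P10/P90) bound the envelope per
county × year.

A synthetic-data module generates a full study region — counties nested in
cities, degraded observation tables, a population raster with nulls and
inconsistent totals — together with its exact ground truth, so the whole
pipeline is testable offline.

## Worked example

```python
from mehgrid import make_region, simulate_inputs
from mehgrid.pipeline import run_full
from mehgrid.spatialize import conservation_diagnostics

region = make_region(n_cities=2, counties_per_city=2, grid_shape=(20, 20), seed=42)
inputs = simulate_inputs(region, (2009, 2019), noise_cv=0.1, seed=42)
county_edi, rasters = run_full(inputs)

print(county_edi.head(6).to_string(index=False))
year = 2011
control = county_edi.query("year == @year").set_index("county")["edi"]
diag = conservation_diagnostics(rasters[("all", year)], region.zone_grid, control)
print(f"2011 mean county EDI: {control.mean():.4f} ug/kg/d")
print(f"max conservation error after gridding: {diag['rel_error'].max():.2e}")
```

prints

```
 county  year      edi
      1  2009 0.011992
      2  2009 0.012016
      3  2009 0.012299
      4  2009 0.012997
      1  2010 0.014800
      2  2010 0.014834
2011 mean county EDI: 0.0155 ug/kg/d
max conservation error after gridding: 2.26e-16
```

Each `edi` value is a per-capita daily MeHg dose in μg per kg body weight:
county 1's 0.012 μg kg⁻¹ d⁻¹ in 2009 is the urbanization-weighted mix of
its city's urban and rural EDIs for that year. The conservation error shows
that the 2011 raster redistributes each county's EDI across its cells
without creating or losing exposure. The same workflow is available from
the shell (`mehgrid simulate | inventory | spatialize | uncertainty |
run-all`), writing per-year `<region>/<year>.tif` rasters plus a manifest.

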