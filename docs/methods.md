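# Methods

## Scope and model

`mehgrid` constructs a time-series, county-resolved inventory of dietary
methylmercury (MeHg) exposure and downscales it to grid cells. Exposure is
expressed as the estimated daily intake (EDI), a per-capita dose in
μg MeHg per kg body weight per day. The food scope is deliberately narrow —
rice and fish (freshwater and marine), the two dominant dietary MeHg
carriers — and all formulas are linear in both concentrations and intakes,
which drives most of the testable structure (scaling invariances, convex
bounds, conservation).

The chain is:

1. **Concentration completion.** Literature MeHg concentrations arrive as
   scattered annual values per food. Duplicates within a (food, year) are
   arithmetic-averaged. Interior gaps between observed years `a < b` are
   filled linearly, `v(t) = v(a) + (v(b) − v(a))·(t−a)/(b−a)`; for the
   common 4-year gap this is the 0.25/0.5/0.75 weighting. Years outside
   the observed span are filled assuming the change rate of the nearest
   adjacent observed pair persists.
2. **Inventory.** `I_ij = CON_ij·NI_i/NCON_i` converts per-capita
   consumption to intake with a national intake/consumption ratio;
   `EDI_j = Σ_i I_ij·C_i/BW` gives city urban/rural EDIs;
   `EDI_n = UEDI_j·r + REDI_j·(1−r)` mixes them into county EDIs by
   urbanization rate. A county EDI is therefore always a convex
   combination of its city's two sector EDIs.
3. **Gridding.** County EDI is allocated to cells proportionally to a
   food-expenditure proxy: gridded population (nulls zeroed inside
   counties), calibrated per county to official totals
   (`p_ni = g_ni·pop_n/Σg_ni`), times per-capita food expenditure
   (`CON_ni = p_ni·pCON_n`), normalized within the county
   (`EDI_ni = EDI_n·CON_ni/ΣCON_ni`).
4. **Uncertainty.** Monte Carlo perturbation of concentrations, intakes
   and body weight, re-running steps 2–3's arithmetic per draw;
   P10/P90 of the draws bound the envelope.

## Design choices on genuinely open points

- **Edge extrapolation rate.** "Constant change rate" can mean a ratio or
  an absolute difference. The default is the *ratio* of the nearest
  adjacent observed pair, applied repeatedly for multi-year edges
  (`v(last+k) = v(last)·g^k`, `v(first−k) = v(first)/g^k`), because a
  multiplicative rate preserves positivity of concentrations. An
  absolute-difference mode (clipped at zero) is available via
  `mode="difference"`. A ratio with a zero base is undefined; the series
  then extends as a constant and the year is noted in the series' audit
  notes.
- **Body weight.** The denominator defaults to the simple mean of the
  published male (66.2 kg) and female (57.3 kg) adult means, 61.75 kg; a
  population-weighted value can be passed via `BodyWeight(effective_kg=…)`.
- **Unit conventions.** Annual consumption converts at 1000/365
  g d⁻¹ per kg yr⁻¹; intake grams convert to kilograms inside the EDI
  formula so outputs are μg kg⁻¹ d⁻¹ throughout.
- **GDP similarity window.** Consumption for a missing city is the
  per-food mean over donor cities whose per-capita GDP is within ±20%
  (relative) of the target's; the window widens once (to ±40%) before
  failing. The level-city/structure-city override reproduces the pattern
  of borrowing one city's total consumption level and another's dietary
  composition.
- **Disaggregation order.** Aggregated food categories are split by
  expenditure/price-implied quantities first, by production shares
  otherwise; both rescale so components sum exactly to the aggregate.
  All-zero weights fall back to an equal split with a logged warning.
- **Counties with zero proxy mass.** A county whose cleaned population
  raster sums to zero but whose control total (population or EDI) is
  positive receives a uniform spread over its cells. Conservation is
  treated as non-negotiable; the fallback is logged.
- **Merged counties.** Counties folded into a neighbour (the situation of
  districts inaugurated too recently for separate statistics) merge by
  population-weighted EDI and urbanization rate and summed population.
- **Grid output semantics.** Raster cells carry *allocation shares* of the
  county EDI (cells of a county sum to `EDI_n`); a per-capita
  interpretation (`per_capita_grid`) is offered as a clearly separate
  output mode.

## Monte Carlo assumptions

The input noise distributions are not identifiable from published
material, so they are explicit, configurable assumptions:

- concentrations and consumption: multiplicative lognormal noise with a
  stated coefficient of variation (CV), parameterized to preserve the
  median (`μ = ln(central)`, `σ² = ln(1+CV²)`). Median-preservation means
  the point estimate is the median of the predictive draws, so a
  single-factor [P10, P90] band has exactly 0.80 nominal coverage when the
  noise model matches the truth — which makes the coverage validation
  interpretable.
- body weight: normal around 1 with the stated CV, redrawn on
  non-positive values (effectively zero-truncated); default fixed.
- draw count: 10,000 by default; percentiles use the linear-interpolation
  empirical quantile.
- seeding: each perturbed variable owns a child stream
  (`SeedSequence(seed, spawn_key=(k,))` with a fixed per-variable key), so
  adding or removing a variable never reshuffles another variable's draws
  and fixed seeds reproduce envelopes bit-identically.

## The synthetic generator

The generator emulates the *structure* of the real input landscape, not
its geography or magnitudes:

- counties are axis-aligned rectangular tiles of a jittered checkerboard,
  nested in cities — contiguity is all the math needs; realistic
  boundaries are out of scope;
- true concentration series are **linear in time** per food, so interior
  linear gap-filling recovers deleted years exactly (the recovery test's
  oracle); edge-gap recovery by the ratio rule is consequently only
  approximate and is not asserted exactly;
- consumption is constant over the study period per city × sector × food;
  observation noise is multiplicative lognormal (median-1) with a chosen
  CV; a configurable fraction of food-years carries duplicate
  observations (default 25%);
- the population raster is gamma-distributed per cell with 5% null cells
  inside counties, and official county totals are drawn independently, so
  calibration genuinely has work to do;
- degradation layers (concentration gaps, edge gaps, missing cities,
  aggregated fish rows) draw from a mask stream independent of the truth
  and noise streams, so ground truth is invariant to the missingness
  configuration;
- ground truth (county EDI, completed concentrations, intakes, cell
  allocations) is computed by direct inline arithmetic on the truth
  parameters, never by calling the pipeline under test.

What passing synthetic tests does **not** show: robustness to non-linear
concentration trends, temporally varying consumption, correlated noise
across foods or cities, boundary-straddling grid cells, or the biases of
real yearbook compilation. Those need real data.

## Numerical choices and degenerate inputs

- Conservation (calibration and allocation) is validated at 1e-9 relative
  error per county; in practice it holds at machine precision because the
  scale factor is applied per county in one multiplication.
- The noise-free round trip (pipeline vs ground truth) is validated at
  1e-12 relative for county EDIs and 1e-9 for cell allocations; the
  pipeline and oracle share formulas but not code paths, so agreement is
  limited only by floating-point ordering.
- Cells outside every county zone are nodata (−9999.0) at every stage;
  the zone sentinel is −9999. Rasters are written float32; all in-memory
  arithmetic is float64.
- Zero-population cells receive zero EDI; fully null counties degrade to
  uniform spreads as above.
- Degenerate Monte Carlo specs (all CVs zero) collapse P10 = P90 = point
  exactly, because factors of exactly 1.0 leave the einsum path
  bit-identical to the point computation.

## Validation problem sizes

Conservation properties run on a 21-county, 110×110 region (≈10,500
in-county cells, 11 years); recovery on a 12-county 60×60 region; envelope
coverage pools 30 independent replicate regions of 8 counties × 11 years
(2,640 county-years, 1,000 draws each) — county-years within one
realization share concentration noise, so replication across regions is
what actually shrinks the Monte Carlo error of the coverage estimate.

## Known limitations

- Real-mode inputs (yearbook tables, LandScan GeoTIFFs, administrative
  boundary rasterization, wet/dry-weight unit reconciliation of literature
  concentrations) are out of scope; the loaders accept the documented CSV
  and TIFF schemas only.
- Raster georeferencing is a minimal geometry record (origin, cell size,
  CRS tag) carried in TIFF metadata and the dataset manifest; there is no
  reprojection or resampling.
- The edge-extrapolation and GDP-window rules are single defaults over
  genuinely ambiguous methodology; sensitivity to them is the user's
  responsibility to explore (both are exposed as parameters).
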