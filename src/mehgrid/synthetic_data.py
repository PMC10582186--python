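"""Synthetic study region with known ground-truth exposure.

Emulates the input landscape of a county-level dietary-exposure study —
sparse literature concentration series with duplicate years and gaps,
urban/rural consumption yearbook tables with missing cities and aggregated
fish categories, a population raster with null cells whose county sums
disagree with official totals, and per-county food-expenditure levels —
for a rectangular region of counties nested in cities.

Ground truth (county EDI per year, complete concentration series, intakes,
and cell-level allocations) is computed by direct arithmetic on the
noise-free generator parameters, never by the pipeline under test, so
recovery tests have an independent oracle. True concentration series are
linear in time per food; with zero noise and zero missingness the observed
tables equal ground truth exactly.

Randomness is split into three independent child streams of the seed —
truth parameters, observation noise, missingness masks — so ground truth
is invariant to the missingness settings and to the noise CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inventory import BodyWeight, ConsumptionTable
from .io import (
    KG_PER_YEAR_TO_G_PER_DAY,
    NO_ZONE,
    GridGeometry,
    write_raster,
)

DEFAULT_FOODS = ["rice", "freshwater_fish", "marine_fish"]
#: fraction of observed food-years that carry a duplicate observation
_DUPLICATE_FRAC = 0.25
#: fraction of in-county population cells set to null
_NULL_FRAC = 0.05


@dataclass(frozen=True)
class Missingness:
    """Fractions controlling the data-degradation layers.

    ``concentration_gaps`` deletes interior observed years per food (the
    first and last year of the span always survive); ``edge_gap_years``
    drops whole years from each end of the concentration span;
    ``missing_cities`` removes entire cities from the consumption table;
    ``aggregated_categories`` is the probability that a city × sector row
    set reports a single aggregate "fish" row instead of the fish
    components (with expenditure/price columns supplied for splitting).
    """

    concentration_gaps: float = 0.0
    missing_cities: float = 0.0
    aggregated_categories: float = 0.0
    edge_gap_years: int = 0

    def __post_init__(self) -> None:
        for f in (self.concentration_gaps, self.missing_cities, self.aggregated_categories):
            if not (0.0 <= f < 1.0):
                raise ValueError("missingness fractions must lie in [0, 1)")
        if self.edge_gap_years < 0:
            raise ValueError("edge_gap_years must be >= 0")


@dataclass
class RegionSpec:
    """A rectangular study region of counties nested in cities."""

    cities: list[str]
    counties: pd.DataFrame  # county, city, urbanization_rate, population, per_capita_gdp
    zone_grid: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        c = self.counties
        unknown = set(c["city"]) - set(self.cities)
        if unknown:
            raise ValueError(f"counties reference undeclared cities: {sorted(unknown)}")
        r = c["urbanization_rate"]
        if ((r < 0) | (r > 1)).any():
            raise ValueError("urbanization_rate outside [0, 1]")
        if (c["population"] <= 0).any():
            raise ValueError("official population must be positive")
        ids = np.unique(self.zone_grid)
        ids = set(ids[ids != NO_ZONE].tolist())
        declared = set(c["county"].tolist())
        if not ids <= declared:
            raise ValueError(f"zone grid contains undeclared county ids: {sorted(ids - declared)}")

    @property
    def county_ids(self) -> list[int]:
        return self.counties["county"].tolist()


@dataclass
class GroundTruth:
    """Oracle quantities derived from generator parameters only."""

    county_edi: pd.DataFrame  # county, year, edi
    concentrations: pd.DataFrame  # wide year × food, ug/kg
    intake: pd.DataFrame  # city, sector, food, intake (g/d)
    city_edi: pd.DataFrame  # city, sector, year, edi
    cell_edi: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class SyntheticInputs:
    """Everything the pipeline consumes, plus its oracle."""

    region: RegionSpec
    years: list[int]
    foods: list[str]
    concentration_obs: pd.DataFrame  # food, year, value, source
    consumption: ConsumptionTable  # kg/yr, possibly degraded
    fish_disaggregation: pd.DataFrame  # city, sector, food, expenditure, price
    ratios: pd.DataFrame  # food, national_intake, national_consumption
    population_grid: np.ndarray  # raw, with nulls (nodata)
    expenditure: pd.DataFrame  # county, pcon
    ground_truth: GroundTruth | None = None  # absent when loaded from disk


def make_region(
    n_cities: int,
    counties_per_city: int,
    grid_shape: tuple[int, int],
    seed: int = 0,
    cell_size: float = 1000.0,
) -> RegionSpec:
    """Partition a grid into rectangular county tiles nested in cities.

    Counties are axis-aligned tiles of a jittered checkerboard; leftover
    tiles (when the tile count exceeds the county count) stay outside all
    zones. Deterministic for a fixed seed.
    """
    if n_cities < 1 or counties_per_city < 1:
        raise ValueError("need at least one city and one county per city")
    rows, cols = grid_shape
    n_counties = n_cities * counties_per_city
    tile_rows = max(1, int(np.floor(np.sqrt(n_counties))))
    tile_cols = int(np.ceil(n_counties / tile_rows))
    if rows < tile_rows or cols < tile_cols:
        raise ValueError(
            f"grid {grid_shape} too small for {n_counties} counties "
            f"(needs at least {tile_rows}×{tile_cols} cells)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))

    def _breaks(n: int, k: int) -> np.ndarray:
        # k slabs of >=1 along an axis of length n, jittered
        base = np.linspace(0, n, k + 1).round().astype(int)
        for i in range(1, k):
            lo, hi = base[i - 1] + 1, base[i + 1] - 1
            if hi > lo:
                base[i] = int(np.clip(base[i] + rng.integers(-1, 2), lo, hi))
        return base

    rb = _breaks(rows, tile_rows)
    cb = _breaks(cols, tile_cols)
    zone = np.full((rows, cols), NO_ZONE, dtype=int)
    cid = 0
    for i in range(tile_rows):
        for j in range(tile_cols):
            cid += 1
            if cid > n_counties:
                break
            zone[rb[i]:rb[i + 1], cb[j]:cb[j + 1]] = cid

    cities = [f"city{c:02d}" for c in range(1, n_cities + 1)]
    recs = []
    for c in range(1, n_counties + 1):
        recs.append(
            {
                "county": c,
                "city": cities[(c - 1) // counties_per_city],
                "urbanization_rate": float(rng.uniform(0.2, 0.95)),
                "population": float(rng.integers(50_000, 500_000)),
                "per_capita_gdp": float(rng.uniform(40_000, 160_000)),
            }
        )
    geometry = GridGeometry(rows=rows, cols=cols, cell_size=cell_size)
    return RegionSpec(
        cities=cities,
        counties=pd.DataFrame(recs),
        zone_grid=zone,
        geometry=geometry,
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Median-1 multiplicative lognormal noise; exactly 1 when cv=0."""
    if cv == 0.0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * rng.standard_normal(shape))


def simulate_inputs(
    region: RegionSpec,
    years: tuple[int, int],
    foods: list[str] | None = None,
    missingness: Missingness = Missingness(),
    noise_cv: float = 0.0,
    seed: int = 0,
    bw: BodyWeight = BodyWeight(),
    include_cells: bool = True,
    duplicate_frac: float = _DUPLICATE_FRAC,
) -> SyntheticInputs:
    """Draw a full synthetic input set plus its ground truth.

    ``years`` is an inclusive (start, end) span of at least 3 years. The
    missingness layers degrade the *observed* tables only; ground truth
    depends exclusively on the truth seed stream.
    """
    foods = list(foods) if foods is not None else list(DEFAULT_FOODS)
    y0, y1 = years
    n_years = y1 - y0 + 1
    if n_years < 3:
        raise ValueError("the study period must span at least 3 years")
    span_years = np.arange(y0, y1 + 1)
    keep = n_years - 2 * missingness.edge_gap_years
    if keep < 2 or (n_years - missingness.edge_gap_years * 2 - 2) * (1 - missingness.concentration_gaps) < 0:
        raise ValueError("missingness leaves fewer than 2 observed years per food")

    truth_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    noise_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    mask_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))

    # --- truth: linear concentration series per food (ug/kg), always positive
    base = truth_rng.uniform(2.0, 8.0, len(foods))
    slope = truth_rng.uniform(-0.5, 0.5, len(foods)) * base / n_years
    conc_true = pd.DataFrame(
        base[None, :] + slope[None, :] * (span_years[:, None] - y0),
        index=span_years,
        columns=foods,
    )

    # --- truth: consumption (kg/yr) per city × sector × food, constant in time
    rows = []
    per_food_base = truth_rng.uniform(10.0, 60.0, len(foods))
    for city in region.cities:
        city_level = truth_rng.uniform(0.7, 1.3)
        rural_scale = truth_rng.uniform(0.6, 1.2)
        for k, food in enumerate(foods):
            urban = per_food_base[k] * city_level * truth_rng.uniform(0.8, 1.2)
            rows.append({"city": city, "sector": "urban", "food": food, "value": urban})
            rows.append(
                {"city": city, "sector": "rural", "food": food, "value": urban * rural_scale}
            )
    con_true = pd.DataFrame(rows)

    # --- truth: national intake/consumption ratios
    ncon = truth_rng.uniform(20.0, 60.0, len(foods))
    ratio = truth_rng.uniform(0.6, 1.0, len(foods))
    ratios = pd.DataFrame(
        {"food": foods, "national_intake": ncon * ratio, "national_consumption": ncon}
    )

    # --- truth: per-county per-capita food expenditure (currency/yr)
    pcon = pd.DataFrame(
        {
            "county": region.county_ids,
            "pcon": region.counties["per_capita_gdp"].to_numpy()
            * truth_rng.uniform(0.08, 0.15, len(region.county_ids)),
        }
    )

    # --- truth: raw population raster (before nulls), gamma-distributed
    zone = region.zone_grid
    nodata = region.geometry.nodata
    in_zone = zone != NO_ZONE
    pop_raw = np.full(zone.shape, nodata, dtype=float)
    pop_raw[in_zone] = truth_rng.gamma(2.0, 500.0, int(in_zone.sum()))

    # --- ground-truth EDI by direct arithmetic on truth parameters
    ratio_s = pd.Series(ratio, index=foods)
    intake_true = con_true.assign(
        intake=con_true["value"] * KG_PER_YEAR_TO_G_PER_DAY
        * ratio_s.reindex(con_true["food"]).to_numpy()
    )[["city", "sector", "food", "intake"]]

    ct = intake_true.pivot_table(index=["city", "sector"], columns="food", values="intake")
    ct = ct.reindex(columns=foods)
    city_edi_rows = []
    for (city, sector), intakes in ct.iterrows():
        for year in span_years:
            edi = float(
                np.sum(intakes.to_numpy() * 1e-3 * conc_true.loc[year].to_numpy())
                / bw.effective
            )
            city_edi_rows.append(
                {"city": city, "sector": sector, "year": int(year), "edi": edi}
            )
    city_edi_true = pd.DataFrame(city_edi_rows)
    cw = city_edi_true.pivot_table(index=["city", "year"], columns="sector", values="edi")
    county_rows = []
    for _, cty in region.counties.iterrows():
        r = float(cty["urbanization_rate"])
        for year in span_years:
            u = cw.loc[(cty["city"], year), "urban"]
            ru = cw.loc[(cty["city"], year), "rural"]
            county_rows.append(
                {
                    "county": cty["county"],
                    "year": int(year),
                    "edi": float(u * r + ru * (1 - r)),
                }
            )
    county_edi_true = pd.DataFrame(county_rows)

    # --- noise/missingness layers on observations (mask_rng before noise_rng
    # calls are interleaved deterministically; streams are independent)
    obs_years = span_years[
        missingness.edge_gap_years: n_years - missingness.edge_gap_years
    ]
    obs_rows = []
    for food in foods:
        interior = obs_years[1:-1]
        n_drop = int(np.floor(missingness.concentration_gaps * len(interior)))
        drop = set(
            mask_rng.choice(interior, size=n_drop, replace=False).tolist()
        ) if n_drop else set()
        kept = [y for y in obs_years if y not in drop]
        if len(kept) < 2:
            raise ValueError(f"missingness leaves <2 observed years for {food}")
        dup = mask_rng.random(len(kept)) < duplicate_frac
        for y, d in zip(kept, dup):
            truth = conc_true.loc[y, food]
            obs_rows.append(
                {
                    "food": food,
                    "year": int(y),
                    "value": truth * _lognormal_factors(noise_rng, noise_cv, ())[()],
                    "source": "synthetic-survey-a",
                }
            )
            if d:
                obs_rows.append(
                    {
                        "food": food,
                        "year": int(y),
                        "value": truth * _lognormal_factors(noise_rng, noise_cv, ())[()],
                        "source": "synthetic-survey-b",
                    }
                )
    concentration_obs = pd.DataFrame(obs_rows)

    con_obs = con_true.copy()
    con_obs["value"] = con_obs["value"] * _lognormal_factors(
        noise_rng, noise_cv, len(con_obs)
    )

    # aggregated "fish" rows: replace fish components with their sum; the
    # expenditure/price sidecar allows exact share-preserving disaggregation
    fish_components = [f for f in foods if "fish" in f]
    prices = pd.Series(
        truth_rng.uniform(10.0, 40.0, len(fish_components)), index=fish_components
    )
    agg_rows, side_rows = [], []
    if len(fish_components) >= 2 and missingness.aggregated_categories > 0:
        pieces = []
        for (city, sector), grp in con_obs.groupby(["city", "sector"]):
            if mask_rng.random() < missingness.aggregated_categories:
                fish = grp[grp["food"].isin(fish_components)]
                rest = grp[~grp["food"].isin(fish_components)]
                agg_rows.append(
                    {
                        "city": city,
                        "sector": sector,
                        "food": "fish",
                        "value": float(fish["value"].sum()),
                    }
                )
                for _, row in fish.iterrows():
                    side_rows.append(
                        {
                            "city": city,
                            "sector": sector,
                            "food": row["food"],
                            "expenditure": float(row["value"] * prices[row["food"]]),
                            "price": float(prices[row["food"]]),
                        }
                    )
                pieces.append(rest)
            else:
                pieces.append(grp)
        con_obs = pd.concat(pieces + [pd.DataFrame(agg_rows)], ignore_index=True)
    fish_disagg = pd.DataFrame(
        side_rows, columns=["city", "sector", "food", "expenditure", "price"]
    )

    n_missing = int(np.floor(missingness.missing_cities * len(region.cities)))
    if n_missing:
        dropped = set(
            mask_rng.choice(region.cities, size=n_missing, replace=False).tolist()
        )
        con_obs = con_obs[~con_obs["city"].isin(dropped)].reset_index(drop=True)

    # population nulls inside counties
    pop_obs = pop_raw.copy()
    in_idx = np.argwhere(in_zone)
    n_null = int(np.floor(_NULL_FRAC * len(in_idx)))
    if n_null:
        chosen = in_idx[mask_rng.choice(len(in_idx), size=n_null, replace=False)]
        pop_obs[chosen[:, 0], chosen[:, 1]] = nodata

    # --- ground-truth cell allocations by direct arithmetic (Eqs. 4–6 on
    # the observed raster: nulls→0, calibrate, expenditure proxy, share)
    cell_edi: dict[int, np.ndarray] = {}
    if include_cells:
        pcon_s = pcon.set_index("county")["pcon"]
        pop_official = region.counties.set_index("county")["population"]
        cleaned = pop_obs.copy()
        null = (cleaned == nodata) | np.isnan(cleaned)
        cleaned[in_zone & null] = 0.0
        edi_by_year = {
            y: county_edi_true[county_edi_true["year"] == y].set_index("county")["edi"]
            for y in span_years
        }
        for y in span_years:
            grid = np.full(zone.shape, nodata)
            for cid in region.county_ids:
                mask = zone == cid
                g = cleaned[mask]
                mass = g.sum()
                p = (
                    g * (pop_official[cid] / mass)
                    if mass > 0
                    else np.full(g.shape, pop_official[cid] / mask.sum())
                )
                w = p * pcon_s[cid]
                tw = w.sum()
                share = w / tw if tw > 0 else np.full(g.shape, 1.0 / mask.sum())
                grid[mask] = edi_by_year[y][cid] * share
            cell_edi[int(y)] = grid

    truth = GroundTruth(
        county_edi=county_edi_true,
        concentrations=conc_true,
        intake=intake_true,
        city_edi=city_edi_true,
        cell_edi=cell_edi,
    )
    return SyntheticInputs(
        region=region,
        years=list(span_years),
        foods=foods,
        concentration_obs=concentration_obs,
        consumption=ConsumptionTable(con_obs, units="kg_per_year"),
        fish_disaggregation=fish_disagg,
        ratios=ratios,
        population_grid=pop_obs,
        expenditure=pcon,
        ground_truth=truth,
    )


def write_inputs(inputs: SyntheticInputs, outdir: str | Path, overwrite: bool = False) -> Path:
    """Write the synthetic tables and rasters in the real-mode schemas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = inputs.concentration_obs.rename(columns={"value": "value_ug_per_kg"})
    obs.to_csv(outdir / "concentrations.csv", index=False)
    inputs.consumption.data.to_csv(outdir / "consumption_kg_per_year.csv", index=False)
    inputs.ratios.to_csv(outdir / "national_ratios.csv", index=False)
    inputs.region.counties.to_csv(outdir / "counties.csv", index=False)
    inputs.expenditure.to_csv(outdir / "expenditure.csv", index=False)
    if not inputs.fish_disaggregation.empty:
        inputs.fish_disaggregation.to_csv(outdir / "fish_disaggregation.csv", index=False)
    geom = inputs.region.geometry
    write_raster(
        outdir / "population.tif", inputs.population_grid, geom,
        units="persons per cell", overwrite=overwrite,
    )
    write_raster(
        outdir / "zones.tif", inputs.region.zone_grid.astype(float), geom,
        units="county id", overwrite=overwrite,
    )
    return outdir
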