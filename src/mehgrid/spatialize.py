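"""Allocate county EDI to grid cells via calibrated proxies.

Dasymetric downscaling in three steps, each mass-conserving per county
zone:

1. the gridded population (LandScan-like, with null cells) is cleaned
   (in-zone nulls → 0) and calibrated so per-county sums match official
   totals:  p_ni = g_ni * pop_n / sum_i(g_ni);
2. per-capita food consumption expenditure pCON_n turns population into a
   food-expenditure proxy:  CON_ni = p_ni * pCON_n;
3. the county EDI is distributed over cells by expenditure share:
   EDI_ni = EDI_n * CON_ni / sum_i(CON_ni).

Cells outside every county zone stay nodata throughout. Counties whose
proxy mass is zero but whose control total is positive get a uniform
spread over their cells (conservation takes precedence; logged).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .io import NO_ZONE, GridGeometry

logger = logging.getLogger(__name__)


def _zone_ids(zones: np.ndarray) -> np.ndarray:
    ids = np.unique(zones)
    return ids[ids != NO_ZONE]


def clean_population(
    grid: np.ndarray,
    zones: np.ndarray,
    nodata: float,
) -> np.ndarray:
    """Zero out null population cells inside county zones.

    Cells outside all zones keep the nodata marker. NaN cells are treated
    as null. Negative populations are rejected.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != zones.shape:
        raise ValueError("population and zone grids differ in shape")
    in_zone = zones != NO_ZONE
    null = np.isnan(grid) | (grid == nodata)
    if (grid[in_zone & ~null] < 0).any():
        raise ValueError("negative population cell inside a zone")
    out = grid.copy()
    out[in_zone & null] = 0.0
    out[~in_zone] = nodata
    return out


def calibrate_population(
    grid: np.ndarray,
    zones: np.ndarray,
    official: pd.Series,
    nodata: float,
) -> np.ndarray:
    """Scale the gridded population so per-county sums match official totals.

    Per county n: p_ni = g_ni * pop_n / sum_i(g_ni). A county with a
    positive official total but zero grid mass receives a uniform spread
    over its cells (logged). Counties absent from ``official`` raise.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.full_like(grid, nodata)
    for cid in _zone_ids(zones):
        if cid not in official.index:
            raise KeyError(f"no official population for county {cid}")
        mask = zones == cid
        g = grid[mask]
        if np.isnan(g).any() or (g == nodata).any():
            raise ValueError(f"county {cid}: clean the population grid first")
        pop = float(official[cid])
        mass = g.sum()
        if mass > 0:
            out[mask] = g * (pop / mass)
        else:
            logger.warning(
                "county %s: zero gridded population mass; uniform spread of %g",
                cid, pop,
            )
            out[mask] = pop / mask.sum()
    return out


def expenditure_from_engel(
    total_expenditure: pd.Series, engel: pd.Series
) -> pd.Series:
    """Per-capita food expenditure = total per-capita expenditure × Engel share."""
    total_expenditure, engel = total_expenditure.align(engel, join="inner")
    if ((engel < 0) | (engel > 1)).any():
        raise ValueError("Engel coefficients must lie in [0, 1]")
    return total_expenditure * engel


def expenditure_from_income_ratio(
    county_income: pd.Series,
    county_city: pd.Series,
    city_food_expenditure: pd.Series,
    city_income: pd.Series,
) -> pd.Series:
    """Scale county disposable income by the city food-expenditure share.

    The city-level ratio (food expenditure / disposable income) is applied
    to each county's per-capita disposable income.
    """
    ratio = city_food_expenditure / city_income
    if (city_income <= 0).any():
        raise ValueError("city income must be positive")
    r = ratio.reindex(county_city)
    if r.isna().any():
        bad = county_city[r.isna().to_numpy()].iloc[0]
        raise KeyError(f"no city expenditure/income ratio for city {bad}")
    return pd.Series(
        county_income.to_numpy(float) * r.to_numpy(float), index=county_income.index
    )


def estimate_county_expenditure(
    counties: list,
    engel_inputs: pd.DataFrame | None = None,
    income_inputs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble per-county per-capita food expenditure, preferring Engel.

    ``engel_inputs``: index county, columns ``total_expenditure``,
    ``engel``. ``income_inputs``: index county, columns ``income``,
    ``city``, plus attrs-free city tables passed as extra columns
    ``city_food_expenditure`` and ``city_income`` (already joined per
    county). Returns columns ``county``, ``pcon``, ``method``.
    """
    rows = []
    for county in counties:
        if engel_inputs is not None and county in engel_inputs.index:
            e = engel_inputs.loc[county]
            pcon = float(e["total_expenditure"] * e["engel"])
            rows.append({"county": county, "pcon": pcon, "method": "engel"})
        elif income_inputs is not None and county in income_inputs.index:
            i = income_inputs.loc[county]
            pcon = float(i["income"] * i["city_food_expenditure"] / i["city_income"])
            rows.append({"county": county, "pcon": pcon, "method": "income-ratio"})
        else:
            raise ValueError(
                f"county {county}: neither Engel nor income-ratio inputs available"
            )
    out = pd.DataFrame(rows)
    if (out["pcon"] < 0).any():
        raise ValueError("negative per-capita food expenditure")
    return out


def expenditure_grid(
    population: np.ndarray,
    zones: np.ndarray,
    pcon: pd.Series,
    nodata: float,
) -> np.ndarray:
    """Food-expenditure proxy grid: CON_ni = p_ni × pCON_n."""
    population = np.asarray(population, dtype=float)
    out = np.full_like(population, nodata)
    for cid in _zone_ids(zones):
        if cid not in pcon.index:
            raise KeyError(f"no per-capita food expenditure for county {cid}")
        mask = zones == cid
        out[mask] = population[mask] * float(pcon[cid])
    return out


def allocate_edi(
    county_edi: pd.Series,
    proxy: np.ndarray,
    zones: np.ndarray,
    nodata: float,
) -> np.ndarray:
    """Distribute each county's EDI over its cells by proxy share.

    EDI_ni = EDI_n × CON_ni / Σ_i CON_ni, so per-county cell sums equal the
    county value. A county with positive EDI but zero proxy mass falls back
    to a uniform split (logged). Cells outside all zones stay nodata.
    """
    if (county_edi < 0).any():
        bad = county_edi[county_edi < 0].index[0]
        raise ValueError(f"negative EDI for county {bad}")
    proxy = np.asarray(proxy, dtype=float)
    out = np.full_like(proxy, nodata)
    for cid in _zone_ids(zones):
        if cid not in county_edi.index:
            raise KeyError(f"no EDI for county {cid}")
        mask = zones == cid
        w = proxy[mask]
        total = w.sum()
        edi = float(county_edi[cid])
        if total > 0:
            out[mask] = edi * w / total
        else:
            if edi > 0:
                logger.warning(
                    "county %s: zero proxy mass; uniform EDI allocation", cid
                )
            out[mask] = edi / mask.sum()
    return out


def per_capita_grid(
    allocation: np.ndarray,
    population: np.ndarray,
    official: pd.Series,
    zones: np.ndarray,
    nodata: float,
) -> np.ndarray:
    """Alternative output mode: per-capita EDI per cell.

    Rescales the allocated share grid by population share, i.e.
    EDI_n × (proxy share / population share); with a uniform per-capita
    expenditure this is simply the county per-capita EDI at every populated
    cell. Zero-population cells get 0.
    """
    out = np.full_like(np.asarray(allocation, float), nodata)
    for cid in _zone_ids(zones):
        mask = zones == cid
        p = population[mask]
        a = allocation[mask]
        vals = np.zeros_like(p)
        pos = p > 0
        vals[pos] = a[pos] * float(official[cid]) / p[pos]
        out[mask] = vals
    return out


def conservation_diagnostics(
    grid: np.ndarray,
    zones: np.ndarray,
    control: pd.Series,
) -> pd.DataFrame:
    """Per-county relative error between cell sums and control totals."""
    rows = []
    for cid in _zone_ids(zones):
        s = float(grid[zones == cid].sum())
        c = float(control[cid])
        rel = abs(s - c) / abs(c) if c != 0 else abs(s)
        rows.append({"county": cid, "cell_sum": s, "control": c, "rel_error": rel})
    return pd.DataFrame(rows)


def run_spatialization(
    inventory: pd.DataFrame,
    zones: np.ndarray,
    population_grids: Mapping[int, np.ndarray] | np.ndarray,
    official_population: pd.Series,
    pcon: pd.Series,
    geometry: GridGeometry,
    regions: Mapping[str, list] | None = None,
    years: list[int] | None = None,
) -> dict[tuple[str, int], np.ndarray]:
    """Produce one EDI raster per region per year.

    ``inventory`` columns: county, year, edi. ``population_grids`` is
    either one grid reused for all years or a mapping year → grid (raw,
    nulls allowed). ``regions`` maps region names to county-id lists; by
    default a single region covering all counties. Output keys are
    (region, year); cells outside the region's counties are nodata.
    """
    if zones.shape != (geometry.rows, geometry.cols):
        raise ValueError("zone grid does not match the declared geometry")
    all_ids = list(_zone_ids(zones))
    if regions is None:
        regions = {"all": all_ids}
    have_years = {int(y) for y in inventory["year"].unique()}
    if years is None:
        years = sorted(have_years)
    else:
        years = [int(y) for y in years]
        absent = sorted(set(years) - have_years)
        if absent:
            raise KeyError(f"inventory lacks requested years: {absent}")
    nodata = geometry.nodata

    out: dict[tuple[str, int], np.ndarray] = {}
    for year in years:
        if isinstance(population_grids, Mapping):
            if year not in population_grids:
                raise KeyError(f"no population grid for year {year}")
            raw = population_grids[year]
        else:
            raw = population_grids
        if raw.shape != zones.shape:
            raise ValueError(f"population grid for {year} misaligned with zones")
        cleaned = clean_population(raw, zones, nodata)
        calibrated = calibrate_population(cleaned, zones, official_population, nodata)
        proxy = expenditure_grid(calibrated, zones, pcon, nodata)
        sub = inventory[inventory["year"] == year].set_index("county")["edi"]
        missing = set(all_ids) - set(sub.index)
        if missing:
            raise KeyError(
                f"inventory for year {year} lacks counties: {sorted(missing)}"
            )
        full = allocate_edi(sub, proxy, zones, nodata)
        for region, members in regions.items():
            grid = np.full_like(full, nodata)
            mask = np.isin(zones, list(members))
            grid[mask] = full[mask]
            out[(region, year)] = grid
    return out
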