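"""End-to-end orchestration: inputs → county inventory → gridded EDI.

Thin glue over the stage modules, used by the command-line interface and
by recovery tests against synthetic ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pathlib import Path

from . import concentrations as conc_mod
from . import inventory as inv_mod
from . import io as io_mod
from . import spatialize as spat_mod
from .inventory import BodyWeight, ConsumptionTable
from .synthetic_data import RegionSpec, SyntheticInputs


def load_inputs(indir: str | Path, years: tuple[int, int]) -> SyntheticInputs:
    """Load an input directory in the on-disk schemas (no ground truth).

    Expects the files written by :func:`mehgrid.synthetic_data.write_inputs`
    or real-mode tables in the same layout.
    """
    indir = Path(indir)
    obs = io_mod.read_table(indir / "concentrations.csv", "concentrations").rename(
        columns={"value_ug_per_kg": "value"}
    )
    con = pd.read_csv(indir / "consumption_kg_per_year.csv")
    counties = io_mod.read_table(indir / "counties.csv", "counties")
    ratios = io_mod.read_table(indir / "national_ratios.csv", "national_ratios")
    pcon = io_mod.read_table(indir / "expenditure.csv", "expenditure")
    side_path = indir / "fish_disaggregation.csv"
    side = (
        pd.read_csv(side_path)
        if side_path.exists()
        else pd.DataFrame(columns=["city", "sector", "food", "expenditure", "price"])
    )
    pop, geom, _ = io_mod.read_raster(indir / "population.tif")
    zones, _, _ = io_mod.read_raster(indir / "zones.tif")
    region = RegionSpec(
        cities=sorted(counties["city"].unique()),
        counties=counties,
        zone_grid=zones.astype(int),
        geometry=geom,
    )
    return SyntheticInputs(
        region=region,
        years=list(range(years[0], years[1] + 1)),
        foods=sorted(obs["food"].unique()),
        concentration_obs=obs,
        consumption=ConsumptionTable(con, units="kg_per_year"),
        fish_disaggregation=side,
        ratios=ratios,
        population_grid=pop.astype(float),
        expenditure=pcon,
    )


def repair_consumption(
    con: ConsumptionTable,
    cities: list[str],
    fish_disaggregation: pd.DataFrame,
    per_capita_gdp: pd.Series,
    gdp_window: float = 0.2,
) -> ConsumptionTable:
    """Apply the yearbook gap-filling rules to a consumption table.

    Aggregate ``fish`` rows are split into components by expenditure/price
    shares; cities absent from the table are filled from donors of similar
    per-capita GDP.
    """
    df = con.data.copy()
    pieces = []
    for (city, sector), grp in df.groupby(["city", "sector"]):
        agg = grp[grp["food"] == "fish"]
        if agg.empty:
            pieces.append(grp)
            continue
        side = fish_disaggregation[
            (fish_disaggregation["city"] == city)
            & (fish_disaggregation["sector"] == sector)
        ].set_index("food")
        if side.empty:
            raise ValueError(
                f"{city}/{sector}: aggregated fish row without disaggregation inputs"
            )
        comps = inv_mod.disaggregate_by_expenditure(
            float(agg["value"].iloc[0]), side["expenditure"], side["price"]
        )
        rows = pd.DataFrame(
            {
                "city": city,
                "sector": sector,
                "food": comps.index,
                "value": comps.to_numpy(),
            }
        )
        pieces.append(pd.concat([grp[grp["food"] != "fish"], rows], ignore_index=True))
    df = pd.concat(pieces, ignore_index=True)

    repaired = ConsumptionTable(df, units=con.units)
    present = set(df["city"])
    for city in cities:
        if city in present:
            continue
        rows = inv_mod.fill_missing_city(
            repaired, city, per_capita_gdp, rel_window=gdp_window
        )
        repaired = ConsumptionTable(
            pd.concat([repaired.data, rows], ignore_index=True), units=con.units
        )
    return repaired


def city_gdp_from_counties(counties: pd.DataFrame) -> pd.Series:
    """Population-weighted city per-capita GDP from county rows."""
    def _wavg(g: pd.DataFrame) -> float:
        w = g["population"].to_numpy(float)
        return float((g["per_capita_gdp"].to_numpy(float) * w).sum() / w.sum())

    return counties.groupby("city").apply(_wavg, include_groups=False)


def run_inventory(
    inputs: SyntheticInputs,
    bw: BodyWeight = BodyWeight(),
    edge_mode: str = "ratio",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the county × year EDI inventory from raw synthetic inputs.

    Returns ``(county_edi, completed_concentrations)`` where the first has
    columns county, year, edi and the second is a wide year × food frame.
    """
    y0, y1 = inputs.years[0], inputs.years[-1]
    obs = inputs.concentration_obs
    series = conc_mod.complete_series(obs, (y0, y1), mode=edge_mode)
    conc_wide = conc_mod.series_to_frame(series)

    gdp = city_gdp_from_counties(inputs.region.counties)
    con = repair_consumption(
        inputs.consumption,
        inputs.region.cities,
        inputs.fish_disaggregation,
        gdp,
    )
    intake = inv_mod.derive_intake(con, inputs.ratios)

    frames = []
    for year in inputs.years:
        city_edi = inv_mod.compute_city_edi(intake, conc_wide.loc[year], bw=bw)
        county = inv_mod.compute_county_edi(inputs.region.counties, city_edi)
        frames.append(county.assign(year=int(year))[["county", "year", "edi"]])
    return pd.concat(frames, ignore_index=True), conc_wide


def run_full(
    inputs: SyntheticInputs,
    bw: BodyWeight = BodyWeight(),
    edge_mode: str = "ratio",
    regions: dict[str, list] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, int], np.ndarray]]:
    """Inventory plus spatialization; returns (county EDI, rasters)."""
    county_edi, _ = run_inventory(inputs, bw=bw, edge_mode=edge_mode)
    region = inputs.region
    rasters = spat_mod.run_spatialization(
        county_edi,
        region.zone_grid,
        inputs.population_grid,
        region.counties.set_index("county")["population"],
        inputs.expenditure.set_index("county")["pcon"],
        region.geometry,
        regions=regions,
    )
    return county_edi, rasters
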