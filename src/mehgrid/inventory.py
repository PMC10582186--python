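"""County-level dietary MeHg estimated daily intake (EDI).

The inventory chain: per-capita food consumption by city × sector
(urban/rural) is converted to per-capita intake with a national
intake-to-consumption ratio; intake times food MeHg concentration, summed
over foods and normalized by adult body weight, gives the city urban/rural
EDIs; a county's EDI is the urbanization-rate-weighted mix of its city's
urban and rural EDIs:

    I_ij   = CON_ij * NI_i / NCON_i                 (g d-1 capita-1)
    EDI_j  = sum_i(I_ij * C_i) / BW                 (ug kg-1 d-1)
    EDI_n  = UEDI_j * r + REDI_j * (1 - r)

Consumption tables from statistical yearbooks need patching before these
formulas apply: aggregated categories (e.g. "fish" covering freshwater and
marine fish) are split by expenditure/price or by production shares, and
cities with no table at all are filled from cities of similar per-capita
GDP, or from an explicit level-city/structure-city pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import KG_PER_YEAR_TO_G_PER_DAY

logger = logging.getLogger(__name__)

#: published mean body weights of Chinese adults (kg)
MALE_BW_KG = 66.2
FEMALE_BW_KG = 57.3


@dataclass(frozen=True)
class BodyWeight:
    """Adult body weight used as the EDI denominator.

    The effective weight defaults to the simple mean of the male and female
    means; pass ``effective_kg`` to override (e.g. a population-weighted
    value).
    """

    male_kg: float = MALE_BW_KG
    female_kg: float = FEMALE_BW_KG
    effective_kg: float | None = None

    def __post_init__(self) -> None:
        if self.male_kg <= 0 or self.female_kg <= 0:
            raise ValueError("body weights must be positive")
        if self.effective_kg is not None and self.effective_kg <= 0:
            raise ValueError("effective body weight must be positive")

    @property
    def effective(self) -> float:
        if self.effective_kg is not None:
            return self.effective_kg
        return 0.5 * (self.male_kg + self.female_kg)


@dataclass
class ConsumptionTable:
    """Per-capita food consumption by city × sector × food.

    ``data`` columns: ``city``, ``sector`` (urban/rural), ``food``,
    ``value``. ``units`` is declared once for the whole table and must be
    ``'kg_per_year'`` or ``'g_per_day'``.
    """

    data: pd.DataFrame
    units: str = "g_per_day"

    def __post_init__(self) -> None:
        if self.units not in ("kg_per_year", "g_per_day"):
            raise ValueError(f"unknown units '{self.units}'")
        if (self.data["value"] < 0).any():
            raise ValueError("negative consumption value")

    def to_g_per_day(self) -> "ConsumptionTable":
        if self.units == "g_per_day":
            return self
        df = self.data.assign(value=self.data["value"] * KG_PER_YEAR_TO_G_PER_DAY)
        return ConsumptionTable(df, units="g_per_day")


def derive_intake(con: ConsumptionTable, ratios: pd.DataFrame) -> pd.DataFrame:
    """Convert consumption to intake with national intake/consumption ratios.

    ``ratios`` columns: ``food``, ``national_intake``, ``national_consumption``
    (any common unit). Output columns: city, sector, food, ``intake``
    (g d⁻¹ capita⁻¹).
    """
    con = con.to_g_per_day()
    if (ratios["national_consumption"] <= 0).any():
        raise ValueError("national consumption must be positive")
    rmap = (ratios["national_intake"] / ratios["national_consumption"]).to_numpy()
    ratio = pd.Series(rmap, index=ratios["food"])
    missing = set(con.data["food"]) - set(ratio.index)
    if missing:
        raise KeyError(f"no national intake/consumption ratio for foods: {sorted(missing)}")
    out = con.data.copy()
    out["intake"] = out["value"].to_numpy() * ratio.reindex(out["food"]).to_numpy()
    return out[["city", "sector", "food", "intake"]]


def disaggregate_by_expenditure(
    aggregate: float,
    expenditures: pd.Series,
    prices: pd.Series,
) -> pd.Series:
    """Split an aggregate consumption quantity by expenditure/price shares.

    Monetary per-capita expenditure on each component food divided by its
    consumer price gives implied physical quantities; their shares rescale
    the aggregate so the components sum to it exactly. If every component
    expenditure is zero the split degenerates to equal shares (warned).
    """
    if aggregate < 0:
        raise ValueError("aggregate consumption must be >= 0")
    expenditures, prices = expenditures.align(prices, join="inner")
    if (prices <= 0).any():
        raise ValueError("component prices must be positive")
    if (expenditures < 0).any():
        raise ValueError("component expenditures must be >= 0")
    quantities = expenditures / prices
    total = quantities.sum()
    if total == 0:
        logger.warning("all component expenditures zero; equal split fallback")
        shares = pd.Series(1.0 / len(quantities), index=quantities.index)
    else:
        shares = quantities / total
    return shares * aggregate


def disaggregate_by_production(aggregate: float, production: pd.Series) -> pd.Series:
    """Split an aggregate consumption quantity by production shares."""
    if aggregate < 0:
        raise ValueError("aggregate consumption must be >= 0")
    if (production < 0).any():
        raise ValueError("production must be >= 0")
    total = production.sum()
    if total == 0:
        logger.warning("zero total production; equal split fallback")
        shares = pd.Series(1.0 / len(production), index=production.index)
    else:
        shares = production / total
    return shares * aggregate


def disaggregate(
    aggregate: float,
    expenditures: pd.Series | None = None,
    prices: pd.Series | None = None,
    production: pd.Series | None = None,
) -> pd.Series:
    """Split an aggregate, preferring expenditure/price, else production."""
    if expenditures is not None and prices is not None:
        return disaggregate_by_expenditure(aggregate, expenditures, prices)
    if production is not None:
        return disaggregate_by_production(aggregate, production)
    raise ValueError("need expenditures+prices or production to disaggregate")


def fill_missing_city(
    con: ConsumptionTable,
    target_city: str,
    per_capita_gdp: pd.Series,
    rel_window: float = 0.2,
    level_city: str | None = None,
    structure_city: str | None = None,
) -> pd.DataFrame:
    """Construct consumption rows for a city absent from the table.

    Default rule: per-(sector, food) average over donor cities whose
    per-capita GDP lies within ``rel_window`` relative distance of the
    target's. If no donor qualifies the window is widened once (doubled)
    before failing with a diagnostic.

    Override rule (used in the source dataset for Macao, with Hong Kong as
    the level city and Zhuhai as the structure city): take the per-sector
    total consumption level of ``level_city`` and distribute it over foods
    using the per-food shares of ``structure_city``.
    """
    df = con.data
    if target_city in set(df["city"]):
        raise ValueError(f"{target_city} already has consumption data")

    if (level_city is None) != (structure_city is None):
        raise ValueError("level_city and structure_city must be given together")

    if level_city is not None:
        rows = []
        for sector in ("urban", "rural"):
            lvl = df[(df["city"] == level_city) & (df["sector"] == sector)]
            stru = df[(df["city"] == structure_city) & (df["sector"] == sector)]
            if lvl.empty or stru.empty:
                continue
            total = lvl["value"].sum()
            shares = stru.set_index("food")["value"]
            shares = shares / shares.sum()
            for food, share in shares.items():
                rows.append(
                    {"city": target_city, "sector": sector, "food": food,
                     "value": total * share}
                )
        if not rows:
            raise ValueError(
                f"level city {level_city} / structure city {structure_city} "
                "have no usable consumption rows"
            )
        return pd.DataFrame(rows)

    if target_city not in per_capita_gdp.index:
        raise KeyError(f"no per-capita GDP for {target_city}")
    gdp_t = per_capita_gdp[target_city]
    candidates = per_capita_gdp.drop(index=target_city)
    candidates = candidates[candidates.index.isin(df["city"])]

    for window in (rel_window, 2 * rel_window):
        donors = candidates[(candidates - gdp_t).abs() <= window * gdp_t].index
        if len(donors):
            if window != rel_window:
                logger.warning(
                    "%s: GDP window widened to ±%.0f%% to find donors",
                    target_city, 100 * window,
                )
            donor_rows = df[df["city"].isin(donors)]
            out = (
                donor_rows.groupby(["sector", "food"], as_index=False)["value"]
                .mean()
                .assign(city=target_city)
            )
            return out[["city", "sector", "food", "value"]]
    raise ValueError(
        f"no donor city within ±{200 * rel_window:.0f}% per-capita GDP of "
        f"{target_city} (target GDP {gdp_t:g})"
    )


def compute_city_edi(
    intake: pd.DataFrame,
    concentrations: pd.Series,
    bw: BodyWeight = BodyWeight(),
) -> pd.DataFrame:
    """City urban/rural EDI for one year (μg kg⁻¹ d⁻¹).

    ``intake`` columns city, sector, food, intake (g d⁻¹);
    ``concentrations`` is per-food MeHg (μg kg⁻¹). Intake grams are
    converted to kilograms so the output unit is μg MeHg per kg body
    weight per day.
    """
    consumed = intake[intake["intake"] > 0]
    missing = set(consumed["food"]) - set(concentrations.index)
    if missing:
        raise KeyError(f"no concentration for consumed foods: {sorted(missing)}")
    conc = concentrations.reindex(intake["food"]).fillna(0.0).to_numpy()
    dose = intake["intake"].to_numpy() * 1e-3 * conc  # ug d-1 capita-1
    out = intake.assign(dose=dose)
    edi = (
        out.groupby(["city", "sector"], as_index=False)["dose"]
        .sum()
        .rename(columns={"dose": "edi"})
    )
    edi["edi"] = edi["edi"] / bw.effective
    return edi


def city_edi_wide(city_edi: pd.DataFrame) -> pd.DataFrame:
    """Pivot city × sector EDI into columns ``uedi`` / ``redi``."""
    wide = city_edi.pivot(index="city", columns="sector", values="edi")
    wide = wide.rename(columns={"urban": "uedi", "rural": "redi"})
    if "uedi" not in wide or "redi" not in wide or wide.isna().any().any():
        raise ValueError("every city needs both an urban and a rural EDI")
    return wide[["uedi", "redi"]]


def compute_county_edi(counties: pd.DataFrame, city_edi: pd.DataFrame) -> pd.DataFrame:
    """Mix city urban/rural EDIs into county EDIs via urbanization rates.

    ``counties`` columns: ``county``, ``city``, ``urbanization_rate``;
    ``city_edi`` as returned by :func:`compute_city_edi`. Output adds
    ``edi`` = UEDI·r + REDI·(1−r).
    """
    r = counties["urbanization_rate"]
    if ((r < 0) | (r > 1)).any():
        bad = counties[(r < 0) | (r > 1)].iloc[0]
        raise ValueError(
            f"urbanization rate {bad['urbanization_rate']} outside [0, 1] "
            f"for county {bad['county']}"
        )
    wide = city_edi_wide(city_edi)
    missing = set(counties["city"]) - set(wide.index)
    if missing:
        raise KeyError(f"no city EDI for cities: {sorted(missing)}")
    uedi = wide["uedi"].reindex(counties["city"]).to_numpy()
    redi = wide["redi"].reindex(counties["city"]).to_numpy()
    rv = r.to_numpy(float)
    out = counties.copy()
    out["edi"] = uedi * rv + redi * (1.0 - rv)
    return out


def merge_counties(
    counties: pd.DataFrame,
    merge_map: dict[str, list],
) -> pd.DataFrame:
    """Merge counties that lack separate official statistics.

    ``merge_map`` maps a surviving county id to the list of member county
    ids (which may include the survivor itself). Members must share a city.
    Merged population is the sum; merged EDI and urbanization rate are
    population-weighted means.
    """
    df = counties.set_index("county")
    merged_away: set = set()
    rows = []
    for new_id, members in merge_map.items():
        missing = [m for m in members if m not in df.index]
        if missing:
            raise KeyError(f"merge map references unknown counties: {missing}")
        sub = df.loc[members]
        if sub["city"].nunique() > 1:
            raise ValueError(
                f"cannot merge counties from different cities: {sorted(set(sub['city']))}"
            )
        pop = sub["population"].to_numpy(float)
        w = pop / pop.sum()
        row = {
            "county": new_id,
            "city": sub["city"].iloc[0],
            "population": float(pop.sum()),
            "urbanization_rate": float((w * sub["urbanization_rate"]).sum()),
        }
        if "edi" in sub:
            row["edi"] = float((w * sub["edi"]).sum())
        if "per_capita_gdp" in sub:
            row["per_capita_gdp"] = float((w * sub["per_capita_gdp"]).sum())
        rows.append(row)
        merged_away.update(members)
    keep = df.drop(index=[m for m in merged_away if m in df.index]).reset_index()
    out = pd.concat([keep, pd.DataFrame(rows)], ignore_index=True)
    return out
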