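"""Hierarchical roll-up, rankings, per-capita rates and sensitivity runs.

City-level attributable deaths are summed to province, region and national
totals on unrounded values (summation order fixed by sorted unit id, so
conservation is exact in floating point).  Counterfactual scenarios total
only below-target cities: each city's contribution is clipped at zero
before summing, while the per-city rows keep their signed values.
Rounding (half away from zero) happens only at presentation.

A packaged reference table of published province/region-level totals for
the 390-city China assessment is included so the aggregation arithmetic
can be cross-checked against printed values.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .hia import ERF, SCENARIOS, run_hia

logger = logging.getLogger("greenhia")

CLIP_SCENARIOS = ("counterfactual_2000", "counterfactual_2010")


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (presentation rounding)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


def build_hierarchy(cities) -> pd.DataFrame:
    """city_id -> (province, region) mapping from a list of cities."""
    return pd.DataFrame(
        [
            {"city_id": c.city_id, "province": c.province, "region": c.region}
            for c in cities
        ]
    )


def aggregate(
    results: pd.DataFrame,
    hierarchy: pd.DataFrame,
    *,
    clip_scenarios: tuple[str, ...] = CLIP_SCENARIOS,
) -> pd.DataFrame:
    """Roll city-level results up to province, region and national rows.

    ``results`` needs city_id, scenario, deaths and (optionally)
    adult_pop columns; ``hierarchy`` maps every city to exactly one
    province and region.  Only leaf cities are summed, so municipality
    province-units (one city = one province) are never double counted.
    Raises on cities absent from the hierarchy, listing them.
    """
    orphans = sorted(set(results["city_id"]) - set(hierarchy["city_id"]))
    if orphans:
        raise ValueError(f"cities missing from the hierarchy: {orphans}")
    merged = results.merge(hierarchy, on="city_id", validate="many_to_one")
    merged = merged.sort_values(["scenario", "city_id"]).reset_index(drop=True)
    if "adult_pop" not in merged:
        merged["adult_pop"] = np.nan
    merged["contribution"] = np.where(
        merged["scenario"].isin(clip_scenarios),
        np.clip(merged["deaths"], 0.0, None),
        merged["deaths"],
    )

    # sums roll up level by level (cities -> provinces -> regions -> national,
    # each in sorted child order) so conservation is exact in floating point
    rows = []
    for row in merged.itertuples(index=False):
        rows.append(
            {
                "unit_id": row.city_id,
                "level": "city",
                "scenario": row.scenario,
                "province": row.province,
                "region": row.region,
                "population": row.adult_pop,
                "deaths": row.deaths,
            }
        )
    for scenario, sgrp in merged.groupby("scenario", sort=True):
        province_rows = []
        for province, grp in sgrp.groupby("province", sort=True):
            province_rows.append(
                {
                    "unit_id": province,
                    "level": "province",
                    "scenario": scenario,
                    "province": province,
                    "region": grp["region"].iloc[0],
                    "population": grp["adult_pop"].sum(),
                    "deaths": grp["contribution"].sum(),
                }
            )
        pframe = pd.DataFrame(province_rows)
        region_rows = []
        for region, grp in pframe.groupby("region", sort=True):
            region_rows.append(
                {
                    "unit_id": region,
                    "level": "region",
                    "scenario": scenario,
                    "province": "",
                    "region": region,
                    "population": grp["population"].sum(),
                    "deaths": grp["deaths"].sum(),
                }
            )
        rframe = pd.DataFrame(region_rows)
        rows.extend(province_rows)
        rows.extend(region_rows)
        rows.append(
            {
                "unit_id": "National",
                "level": "national",
                "scenario": scenario,
                "province": "",
                "region": "",
                "population": rframe["population"].sum(),
                "deaths": rframe["deaths"].sum(),
            }
        )
    return pd.DataFrame(rows)


def per_capita_rate(deaths, adult_pop):
    """Deaths per 100,000 adult inhabitants (unrounded)."""
    adult_pop = np.asarray(adult_pop, dtype=float)
    if np.any(adult_pop <= 0):
        raise ValueError("adult population must be positive for per-capita rates")
    return np.asarray(deaths, dtype=float) / adult_pop * 100_000.0


def rank_units(exposures: pd.DataFrame, *, column: str = "weighted_ndvi",
               scope: str | None = None) -> pd.DataFrame:
    """Greenness ranks (1 = greenest) for one year's exposure table.

    ``scope`` optionally names a grouping column (e.g. ``region``) for
    within-scope ranks.  Ties break by unit id, lexicographically, so the
    ranking is a deterministic permutation of 1..n in every scope.
    """
    if exposures.empty:
        raise ValueError("rank_units needs at least one unit")
    df = exposures.copy()

    def _rank(grp: pd.DataFrame) -> pd.Series:
        order = grp.sort_values([column, "city_id"], ascending=[False, True])
        return pd.Series(
            np.arange(1, len(order) + 1), index=order.index, dtype=int
        )

    if scope is None:
        df["rank"] = _rank(df)
    else:
        df["rank"] = (
            df.groupby(scope, group_keys=False)[[column, "city_id"]]
            .apply(_rank)
        )
    return df


def national_totals(aggregated: pd.DataFrame) -> pd.Series:
    nat = aggregated[aggregated["level"] == "national"]
    return nat.set_index("scenario")["deaths"]


def run_sensitivity(
    exposures: pd.DataFrame,
    demographics: pd.DataFrame,
    hierarchy: pd.DataFrame,
    *,
    variant: str,
    erf: ERF = ERF(),
    rr: float | None = None,
    summer_exposures: pd.DataFrame | None = None,
    scenarios=SCENARIOS,
) -> pd.DataFrame:
    """Percent change in national deaths per scenario under one variant.

    Variants: ``unweighted_ndvi`` (simple-mean exposure), ``summer_ndvi``
    (June-August mean composites; pass ``summer_exposures``) and
    ``alternative_erf`` (pass ``rr`` per increment).
    """
    base = run_hia(exposures, demographics, erf, scenarios)
    base_nat = national_totals(aggregate(base, hierarchy))
    if variant == "unweighted_ndvi":
        alt = run_hia(exposures, demographics, erf, scenarios,
                      ndvi_column="unweighted_ndvi")
    elif variant == "summer_ndvi":
        if summer_exposures is None:
            raise ValueError("summer_ndvi variant needs summer_exposures")
        alt = run_hia(summer_exposures, demographics, erf, scenarios)
    elif variant == "alternative_erf":
        if rr is None:
            raise ValueError("alternative_erf variant needs rr")
        alt_erf = ERF(rr, min(rr, erf.ci_low), max(rr, erf.ci_high), erf.increment)
        alt = run_hia(exposures, demographics, alt_erf, scenarios)
    else:
        raise ValueError(f"unknown sensitivity variant {variant!r}")
    alt_nat = national_totals(aggregate(alt, hierarchy))
    rows = []
    for scenario in scenarios:
        b = base_nat.get(scenario, np.nan)
        a = alt_nat.get(scenario, np.nan)
        pct = (a - b) / abs(b) * 100.0 if b not in (0.0, np.nan) and b == b else np.nan
        rows.append(
            {
                "scenario": scenario,
                "variant": variant,
                "base_deaths": b,
                "variant_deaths": a,
                "percent_change": pct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published reference tables (packaged fixtures)
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("greenhia.data").joinpath(name)


def region_province_map() -> pd.DataFrame:
    """The seven-region -> province membership table (packaged fixture)."""
    with resources.as_file(_data_path("region_provinces.csv")) as path:
        return pd.read_csv(path)


def reference_table() -> pd.DataFrame:
    """Published province/region-level totals for the 390-city assessment.

    Columns: level (region|province), region, name, population_2000,
    deaths_2000_2010, population_2010, deaths_2010_2020 — printed values,
    used to cross-check the aggregation arithmetic, never recomputed.
    """
    with resources.as_file(_data_path("reference_totals.csv")) as path:
        return pd.read_csv(path)


def reference_checks() -> dict[str, float]:
    """Machine-checkable sums over the printed reference values.

    Runs the package's own :func:`aggregate` over the printed rows:
    province rows summed to selected regional totals, region rows summed
    to the national totals for both decades, regional populations summed
    to the national 2000 population, and the two decade totals combined
    into the net 2000-2020 figure.
    """
    ref = reference_table()
    regions = ref[ref["level"] == "region"]
    provinces = ref[ref["level"] == "province"]

    # regions -> national, via aggregate() with each region as a leaf unit
    hier = pd.DataFrame(
        {"city_id": regions["name"], "province": regions["name"],
         "region": regions["region"]}
    )
    out: dict[str, float] = {}
    for scenario, col in (
        ("change_2000_2010", "deaths_2000_2010"),
        ("change_2010_2020", "deaths_2010_2020"),
    ):
        res = pd.DataFrame(
            {
                "city_id": regions["name"],
                "scenario": scenario,
                "deaths": regions[col].astype(float),
            }
        )
        agg = aggregate(res, hier, clip_scenarios=())
        out[f"national_deaths_{scenario[7:]}"] = float(
            national_totals(agg)[scenario]
        )
    pop = pd.DataFrame(
        {
            "city_id": regions["name"],
            "scenario": "population",
            "deaths": regions["population_2000"].astype(float),
        }
    )
    out["national_population_2000"] = float(
        national_totals(aggregate(pop, hier, clip_scenarios=()))["population"]
    )

    # provinces -> region, for the exactly-printed regional rows
    phier = pd.DataFrame(
        {"city_id": provinces["name"], "province": provinces["name"],
         "region": provinces["region"]}
    )
    pres = pd.DataFrame(
        {
            "city_id": provinces["name"],
            "scenario": "change_2000_2010",
            "deaths": provinces["deaths_2000_2010"].astype(float),
        }
    )
    agg = aggregate(pres, phier, clip_scenarios=())
    reg_rows = agg[agg["level"] == "region"].set_index("region")["deaths"]
    for region, key in (
        ("North China", "region_north_china_2000_2010"),
        ("Central China", "region_central_china_2000_2010"),
        ("Southwest China", "region_southwest_china_2000_2010"),
        ("Northeast China", "region_northeast_china_2000_2010"),
    ):
        out[key] = float(reg_rows[region])
    pres2 = pres.assign(
        scenario="change_2010_2020",
        deaths=provinces["deaths_2010_2020"].astype(float).to_numpy(),
    )
    agg2 = aggregate(pres2, phier, clip_scenarios=())
    out["region_north_china_2010_2020"] = float(
        agg2[(agg2["level"] == "region")]
        .set_index("region")["deaths"]["North China"]
    )

    out["net_deaths_2000_2020"] = -(
        out["national_deaths_2000_2010"] + out["national_deaths_2010_2020"]
    )
    return out
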