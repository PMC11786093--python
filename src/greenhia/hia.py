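"""Health-impact equations linking NDVI change to attributable mortality.

The exposure-response function (ERF) is a relative risk per fixed NDVI
increment, RR = 0.96 (95% CI 0.94-0.97) per +0.1 NDVI from the pooled
cohort literature: a 0.1-unit greenness gain lowers adult all-cause
mortality risk by 4%.  Risk for an arbitrary change rescales log-linearly,

    RR(delta) = RR_inc ** (delta / increment) = exp(ln(RR_inc)/increment * delta),

the attributable fraction is AF = (RR - 1)/RR, and the annual mortality
burden is M = y0 * Pop * AF with y0 the baseline all-cause mortality rate
of the adult (20+) population.  Negative M means averted deaths.

Four scenarios are assessed: the observed greenness changes over each
decade (2010 minus 2000, 2020 minus 2010) and two counterfactuals in which
every city is lifted to the 75th percentile of the city-level NDVI
distribution of that year (delta = actual - target, so below-target cities
yield RR > 1, i.e. preventable deaths).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("greenhia")

#: Baseline national all-cause mortality rates (deaths per person-year,
#: adult population) for the two scenario base years.
MORTALITY_RATE = {2000: 0.0055, 2010: 0.0043}

SCENARIOS = (
    "change_2000_2010",
    "change_2010_2020",
    "counterfactual_2000",
    "counterfactual_2010",
)

#: scenario -> (kind, years).  Change scenarios pair delta = later - earlier
#: with the earlier year's population and mortality rate; counterfactual
#: scenarios use that same year's population and rate.
SCENARIO_SPECS: dict[str, tuple[str, tuple[int, ...]]] = {
    "change_2000_2010": ("change", (2000, 2010)),
    "change_2010_2020": ("change", (2010, 2020)),
    "counterfactual_2000": ("counterfactual", (2000,)),
    "counterfactual_2010": ("counterfactual", (2010,)),
}


@dataclass(frozen=True)
class ERF:
    """Relative risk per NDVI increment, with its 95% CI.

    Defaults encode RR = 0.96 (0.94-0.97) per +0.1 NDVI.
    """

    rr_per_increment: float = 0.96
    ci_low: float = 0.94
    ci_high: float = 0.97
    increment: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_low <= self.rr_per_increment <= self.ci_high):
            raise ValueError(
                "ERF requires 0 < ci_low <= rr_per_increment <= ci_high"
            )
        if self.increment <= 0:
            raise ValueError("ERF increment must be positive")

    @property
    def log_sd(self) -> float:
        """Standard deviation of ln(RR) implied by the normal-on-log 95% CI."""
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * 1.959963984540054)

    @property
    def beta(self) -> float:
        """Log relative risk per one NDVI unit, ln(RR_inc)/increment."""
        return math.log(self.rr_per_increment) / self.increment


def rr_from_change(change, erf: ERF = ERF()):
    """Relative risk for an observed NDVI change: RR_inc ** (change/increment)."""
    return erf.rr_per_increment ** (np.asarray(change, dtype=float) / erf.increment)


def rr_from_difference(difference, erf: ERF = ERF()):
    """Relative risk for an actual-minus-target difference.

    Log-linear form exp(ln(RR_inc)/increment * difference); algebraically
    identical to :func:`rr_from_change`, kept as a named operation so both
    published forms are implemented and cross-checkable.
    """
    return np.exp(erf.beta * np.asarray(difference, dtype=float))


def attributable_fraction(rr):
    """AF = (RR - 1)/RR; the share of deaths attributable to the exposure gap."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("relative risk must be positive")
    return (rr - 1.0) / rr


def attributable_mortality(y0, adult_pop, af):
    """Annual attributable deaths M = y0 * Pop * AF (signed, unrounded)."""
    y0 = np.asarray(y0, dtype=float)
    adult_pop = np.asarray(adult_pop, dtype=float)
    if np.any(y0 <= 0) or np.any(y0 >= 1):
        raise ValueError("y0 must lie in (0, 1)")
    if np.any(adult_pop < 0):
        raise ValueError("adult population must be non-negative")
    return y0 * adult_pop * np.asarray(af, dtype=float)


def counterfactual_target(city_exposures, percentile: float = 75.0) -> float:
    """Counterfactual greenness target: a percentile of city-level NDVI.

    Linear-interpolation percentile of the city-level weighted-NDVI
    distribution for one year (default 75th, so roughly three quarters of
    cities sit below the target).
    """
    values = np.asarray(city_exposures, dtype=float)
    if values.size == 0:
        raise ValueError("counterfactual target needs at least one city exposure")
    if values.size < 2:
        logger.warning("counterfactual target computed from a single city")
    return float(np.percentile(values, percentile))


def scenario_deltas(
    exposures: pd.DataFrame,
    scenario: str,
    demographics: pd.DataFrame,
    *,
    percentile: float = 75.0,
    ndvi_column: str = "weighted_ndvi",
) -> pd.DataFrame:
    """Build per-city HIA inputs (delta, y0, adult_pop) for one scenario.

    ``exposures`` carries city_id/year/<ndvi_column>/adult_population rows;
    ``demographics`` carries city_id/year/y0.  Cities missing a required
    year are skipped with a logged warning.
    """
    if scenario not in SCENARIO_SPECS:
        raise ValueError(f"unknown scenario {scenario!r}")
    kind, years = SCENARIO_SPECS[scenario]
    base_year = years[0]
    wide = exposures.pivot_table(
        index="city_id", columns="year", values=ndvi_column, aggfunc="first"
    )
    pop = exposures.pivot_table(
        index="city_id", columns="year", values="adult_population", aggfunc="first"
    )
    y0_map = demographics.set_index(["city_id", "year"])["y0"]

    rows = []
    target = None
    if kind == "counterfactual":
        have = wide[base_year].dropna()
        target = counterfactual_target(have.to_numpy(), percentile)
    for city_id in wide.index:
        vals = wide.loc[city_id]
        if any(year not in vals.index or pd.isna(vals[year]) for year in years):
            logger.warning(
                "city %s: missing exposure for scenario %s, skipped", city_id, scenario
            )
            continue
        if kind == "change":
            delta = float(vals[years[1]] - vals[years[0]])
        else:
            delta = float(vals[base_year] - target)
        try:
            y0 = float(y0_map[(city_id, base_year)])
        except KeyError:
            y0 = MORTALITY_RATE[base_year]
        rows.append(
            {
                "city_id": city_id,
                "scenario": scenario,
                "delta": delta,
                "y0": y0,
                "adult_pop": float(pop.loc[city_id, base_year]),
                "target": target if target is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_scenario(inputs: pd.DataFrame, erf: ERF = ERF()) -> pd.DataFrame:
    """Evaluate RR, AF and attributable deaths for prepared scenario inputs."""
    out = inputs.copy()
    rr = rr_from_change(out["delta"].to_numpy(), erf)
    af = attributable_fraction(rr)
    deaths = attributable_mortality(
        out["y0"].to_numpy(), out["adult_pop"].to_numpy(), af
    )
    out["rr"] = rr
    out["af"] = af
    out["deaths"] = deaths
    return out


def run_hia(
    exposures: pd.DataFrame,
    demographics: pd.DataFrame,
    erf: ERF = ERF(),
    scenarios=SCENARIOS,
    *,
    percentile: float = 75.0,
    ndvi_column: str = "weighted_ndvi",
) -> pd.DataFrame:
    """Run every scenario; returns the concatenated per-city result table."""
    frames = []
    for scenario in scenarios:
        inputs = scenario_deltas(
            exposures, scenario, demographics,
            percentile=percentile, ndvi_column=ndvi_column,
        )
        if len(inputs):
            frames.append(run_scenario(inputs, erf))
    if not frames:
        return pd.DataFrame(
            columns=["city_id", "scenario", "delta", "y0", "adult_pop",
                     "target", "rr", "af", "deaths"]
        )
    return pd.concat(frames, ignore_index=True)
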