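"""From raw NDVI scenes to per-city annual exposure records.

Pipeline order: per-scene QA masking and range filtering, per-year median
compositing, per-pixel temporal-consistency screening across the annual
composites, water masking, block aggregation of NDVI to the population
grid, and finally population-weighted and unweighted zonal NDVI,

    weighted NDVI = sum_i(NDVI_i * Pop_i) / sum_i(Pop_i)

over the city's member pixels with valid NDVI.  All masking operations
only set cells to nodata, so QA and range filtering commute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    GridValidationError,
    RasterGrid,
    rasterize_city_mask,
    require_coregistered,
)

logger = logging.getLogger("greenhia")

#: Plausible NDVI range for vegetated surfaces; values strictly outside
#: are treated as sensor/processing artefacts.
NDVI_MIN = -0.2
NDVI_MAX = 1.0

#: Default absolute deviation from the cross-year pixel median beyond which
#: an annual value is considered a sudden, uncharacteristic change.
TEMPORAL_THRESHOLD = 0.3

SUMMER_MONTHS = (6, 7, 8)

EXPOSURE_COLUMNS = [
    "city_id", "year", "weighted_ndvi", "unweighted_ndvi",
    "total_population", "adult_population", "n_valid_pixels",
]


class UndefinedExposureError(ValueError):
    """No valid population-NDVI overlap: the exposure is undefined."""


# ---------------------------------------------------------------------------
# Per-scene filters
# ---------------------------------------------------------------------------


def apply_qa_mask(scene: RasterGrid, qa: RasterGrid) -> RasterGrid:
    """Set pixels flagged invalid (qa = 0) to nodata; others pass through."""
    require_coregistered(scene, qa, "scene/QA")
    values = scene.values.copy()
    values[qa.values == 0.0] = scene.nodata
    return scene.with_values(values)


def filter_outliers(grid: RasterGrid) -> RasterGrid:
    """Drop NDVI values outside the vegetated-surface range.

    Values < -0.2 or > 1.0 become nodata; the boundary values themselves
    are retained (the exclusion inequalities are strict).
    """
    if grid.kind not in ("ndvi_scene", "ndvi_composite"):
        raise GridValidationError(f"outlier filter expects NDVI grids, got {grid.kind}")
    values = grid.values.copy()
    valid = grid.valid_mask()
    bad = valid & ((values < NDVI_MIN) | (values > NDVI_MAX))
    values[bad] = grid.nodata
    return grid.with_values(values)


def temporal_consistency_filter(
    series: np.ndarray,
    threshold: float = TEMPORAL_THRESHOLD,
    nodata: float = np.nan,
) -> np.ndarray:
    """Flag sudden departures of one pixel's NDVI series from its median.

    ``series`` holds a pixel's ordered annual values (nodata/NaN allowed).
    A value is flagged invalid iff |value - median(valid series)| exceeds
    ``threshold``.  Series with fewer than 3 valid values pass unflagged
    (counted as a warning by callers); a series whose values are all
    flagged is fully invalid, which the all-True flag vector expresses.

    Returns a boolean array, True = flagged invalid.
    """
    series = np.asarray(series, dtype=float)
    valid = np.isfinite(series) & (series != nodata)
    flags = np.zeros(series.shape, dtype=bool)
    if valid.sum() < 3:
        return flags
    med = np.median(series[valid])
    flags[valid] = np.abs(series[valid] - med) > threshold
    return flags


def apply_temporal_filter(
    composites: list[RasterGrid], threshold: float = TEMPORAL_THRESHOLD
) -> tuple[list[RasterGrid], int]:
    """Apply the per-pixel consistency screen across annual composites.

    Vectorised over the whole grid; returns the filtered composites and the
    count of pixels with too few (<3) valid years to screen.
    """
    for comp in composites[1:]:
        require_coregistered(composites[0], comp, "annual composites")
    stack = np.stack([c.values for c in composites])
    valid = np.stack([c.valid_mask() for c in composites])
    n_valid = valid.sum(axis=0)
    screenable = n_valid >= 3

    work = np.where(valid, stack, np.nan)
    with np.errstate(all="ignore"):
        med = np.nanmedian(work, axis=0)
    dev = np.abs(work - med)
    flags = valid & screenable[None, :, :] & (dev > threshold)

    out = []
    for comp, flag in zip(composites, flags):
        values = comp.values.copy()
        values[flag] = comp.nodata
        out.append(comp.with_values(values))
    short = int((~screenable & (n_valid > 0)).sum())
    if short:
        logger.warning("%d pixels had <3 valid years; passed unscreened", short)
    return out, short


# ---------------------------------------------------------------------------
# Compositing
# ---------------------------------------------------------------------------


def median_composite(scenes: list[RasterGrid]) -> RasterGrid:
    """Per-pixel median of valid observations across one year's scenes.

    A pixel is nodata iff it has no valid observation; even observation
    counts use the midpoint of the two central values.
    """
    if not scenes:
        raise ValueError("median_composite needs at least one scene")
    for scene in scenes[1:]:
        require_coregistered(scenes[0], scene, "scenes")
    stack = np.stack([s.values for s in scenes])
    valid = np.stack([s.valid_mask() for s in scenes])
    work = np.where(valid, stack, np.nan)
    with np.errstate(all="ignore"):
        med = np.nanmedian(work, axis=0)
    med[~valid.any(axis=0)] = scenes[0].nodata
    out = scenes[0].with_values(med, kind="ndvi_composite")
    out.month = None
    return out


def summer_mean_composite(scenes: list[RasterGrid]) -> RasterGrid:
    """Per-pixel mean of valid June-August observations (peak greenness)."""
    summer = [s for s in scenes if s.month in SUMMER_MONTHS]
    if not summer:
        raise ValueError("no June-August scenes available for summer composite")
    for scene in summer[1:]:
        require_coregistered(summer[0], scene, "scenes")
    stack = np.stack([s.values for s in summer])
    valid = np.stack([s.valid_mask() for s in summer])
    total = np.where(valid, stack, 0.0).sum(axis=0)
    count = valid.sum(axis=0)
    mean = np.where(count > 0, total / np.maximum(count, 1), summer[0].nodata)
    out = summer[0].with_values(mean, kind="ndvi_composite")
    out.month = None
    return out


def apply_water_mask(composite: RasterGrid, water: RasterGrid) -> RasterGrid:
    """Set water-body pixels (water = 1) to nodata; blue space is excluded."""
    require_coregistered(composite, water, "composite/water")
    values = composite.values.copy()
    values[water.values == 1.0] = composite.nodata
    return composite.with_values(values)


# ---------------------------------------------------------------------------
# Grid alignment and zonal statistics
# ---------------------------------------------------------------------------


def align_population(pop: RasterGrid, ndvi: RasterGrid) -> RasterGrid:
    """Block-average NDVI up to the population grid.

    The NDVI grid must share the population grid's origin and be finer by
    an exact integer factor k; each population cell receives the mean of
    the valid NDVI pixels in its k-by-k block (nodata if none).  Weighting
    then happens at population resolution, so population mass is conserved
    exactly.  Returns the block-mean NDVI grid on the population template.
    """
    if (pop.origin_x, pop.origin_y) != (ndvi.origin_x, ndvi.origin_y):
        raise GridValidationError("population and NDVI grids must share an origin")
    ratio = pop.pixel_size / ndvi.pixel_size
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise GridValidationError(
            f"pixel-size ratio {ratio} is not a positive integer"
        )
    if ndvi.height != pop.height * k or ndvi.width != pop.width * k:
        raise GridValidationError(
            "NDVI grid shape is not the population shape times the block ratio"
        )
    if k == 1:
        return pop.with_values(ndvi.values.copy(), kind="ndvi_composite")
    valid = ndvi.valid_mask()
    vals = np.where(valid, ndvi.values, 0.0)
    blk_sum = vals.reshape(pop.height, k, pop.width, k).sum(axis=(1, 3))
    blk_n = valid.reshape(pop.height, k, pop.width, k).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        mean = np.where(blk_n > 0, blk_sum / np.maximum(blk_n, 1), pop.nodata)
    out = pop.with_values(mean, kind="ndvi_composite")
    out.year = ndvi.year
    return out


def population_weighted_ndvi(
    ndvi_at_pop_grid: RasterGrid, pop: RasterGrid, city_mask: RasterGrid
) -> float:
    """Population-weighted zonal NDVI over one city's member pixels.

    Pixels with nodata NDVI are excluded from both the numerator and the
    denominator.  Raises :class:`UndefinedExposureError` when the valid
    member pixels carry zero total population.
    """
    require_coregistered(ndvi_at_pop_grid, pop, "NDVI/population")
    require_coregistered(ndvi_at_pop_grid, city_mask, "NDVI/mask")
    member = (city_mask.values == 1.0) & ndvi_at_pop_grid.valid_mask() & pop.valid_mask()
    weights = pop.values[member]
    total = weights.sum()
    if not member.any() or total <= 0:
        raise UndefinedExposureError(
            "zero total population over valid member pixels"
        )
    return float((ndvi_at_pop_grid.values[member] * weights).sum() / total)


def unweighted_ndvi(ndvi: RasterGrid, city_mask: RasterGrid) -> float:
    """Simple (equal-weight) mean NDVI over the city's valid member pixels."""
    require_coregistered(ndvi, city_mask, "NDVI/mask")
    member = (city_mask.values == 1.0) & ndvi.valid_mask()
    if not member.any():
        raise UndefinedExposureError("no valid member pixels")
    return float(ndvi.values[member].mean())


def adult_population(total: float, fraction: float) -> float:
    """Adult (20+) population as total times the census adult fraction."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("adult fraction must lie in [0, 1]")
    return total * fraction


# ---------------------------------------------------------------------------
# Full pipeline over a synthetic (or loaded) study bundle
# ---------------------------------------------------------------------------


def annual_composites_for_city(
    city_data,
    *,
    temporal_threshold: float = TEMPORAL_THRESHOLD,
    summer: bool = False,
) -> dict[int, RasterGrid]:
    """Filtered, water-masked annual composites for one city's scene stack."""
    composites = []
    years = sorted(city_data.scenes)
    for year in years:
        cleaned = []
        for scene, qa in city_data.scenes[year]:
            cleaned.append(filter_outliers(apply_qa_mask(scene, qa)))
        comp = summer_mean_composite(cleaned) if summer else median_composite(cleaned)
        comp.year = year
        composites.append(comp)
    if len(composites) >= 3:
        composites, _ = apply_temporal_filter(composites, temporal_threshold)
    return {
        comp.year: apply_water_mask(comp, city_data.water) for comp in composites
    }


def compute_exposures(
    bundle,
    *,
    temporal_threshold: float = TEMPORAL_THRESHOLD,
    summer: bool = False,
) -> pd.DataFrame:
    """Run the exposure pipeline over every city in a study bundle.

    Returns the exposure table (one row per city-year).  Cities with no
    valid population-NDVI overlap in a year are excluded for that year and
    the exclusion is logged.
    """
    demo = bundle.demographics.set_index(["city_id", "year"])["adult_fraction"]
    rows = []
    for city in bundle.cities:
        data = bundle.city_data[city.city_id]
        composites = annual_composites_for_city(
            data, temporal_threshold=temporal_threshold, summer=summer
        )
        fine_mask = rasterize_city_mask(city, data.water)
        pop_template = data.population[min(data.population)]
        coarse_mask = rasterize_city_mask(city, pop_template)
        for year, comp in composites.items():
            pop = data.population[year]
            ndvi_coarse = align_population(pop, comp)
            try:
                weighted = population_weighted_ndvi(ndvi_coarse, pop, coarse_mask)
                unweighted = unweighted_ndvi(comp, fine_mask)
            except UndefinedExposureError:
                logger.warning(
                    "city %s year %d: undefined exposure, excluded",
                    city.city_id, year,
                )
                continue
            member = (coarse_mask.values == 1.0) & pop.valid_mask()
            total_pop = float(pop.values[member].sum())
            fraction = float(demo[(city.city_id, year)])
            n_valid = int(((fine_mask.values == 1.0) & comp.valid_mask()).sum())
            rows.append(
                {
                    "city_id": city.city_id,
                    "year": year,
                    "weighted_ndvi": weighted,
                    "unweighted_ndvi": unweighted,
                    "total_population": total_pop,
                    "adult_population": adult_population(total_pop, fraction),
                    "n_valid_pixels": n_valid,
                }
            )
    return pd.DataFrame(rows, columns=EXPOSURE_COLUMNS)
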