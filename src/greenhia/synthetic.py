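"""Synthetic study generator emulating the satellite/census input stack.

Builds a self-contained multi-city study with the statistical structure the
analysis assumes: per-city stacks of 16-day-style NDVI scenes (fine grid,
nominally 250 m) contaminated by cloud/QA dropouts, injected out-of-range
outliers and fixed water pixels; quinquennial population grids (coarse
grid, nominally 1 km, integer block ratio to the fine grid) with a
centre-periphery density gradient; city polygons on a flat planar plane;
a demographic table (adult fraction, baseline mortality rate); and a
ground-truth record from which every downstream stage can be checked.

Each city's true NDVI trajectory is linear in year, spatially uniform
within the city, with i.i.d. Gaussian scene noise on top — so the true
annual exposure, trend slope and attributable deaths are known exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from . import hia
from .io_formats import (
    REGIONS,
    City,
    RasterGrid,
    rasterize_city_mask,
    read_keyvalue,
    write_cities,
    write_demographics,
    write_keyvalue,
    write_raster,
)
from .exposure import NDVI_MAX, NDVI_MIN

logger = logging.getLogger("greenhia")

_REGION_LIST = sorted(REGIONS)

#: Baseline mortality rate by survey year (per person-year, adults 20+):
#: the two published anchors (5.5 per thousand in 2000, 4.3 in 2010) with a
#: linear bridge in between and held flat after 2010.
DEFAULT_Y0 = {2000: 0.0055, 2005: 0.0049, 2010: 0.0043, 2015: 0.0043, 2020: 0.0043}


def _y0_for_year(year: int) -> float:
    if year in DEFAULT_Y0:
        return DEFAULT_Y0[year]
    if year <= 2000:
        return 0.0055
    if year >= 2010:
        return 0.0043
    return 0.0055 + (0.0043 - 0.0055) * (year - 2000) / 10.0


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults emulate the real data stack.

    ``grid_size`` is the fine (NDVI) pixels per city tile side;
    ``pop_block`` the fine-to-coarse pixel ratio (4, mirroring 250 m vs
    1 km).  ``trend_mix`` gives the fractions of cities with increasing /
    decreasing / flat true trajectories (greening dominates, as observed
    over 2000-2020).  ``noise_sd`` is the per-scene NDVI noise,
    ``cloud_rate`` the per-scene fraction of QA-invalid pixels,
    ``water_rate`` the fraction of permanent water pixels and
    ``outlier_rate`` the per-scene fraction of injected out-of-range
    values.  ``adult_fraction`` is the population share aged 20+.
    """

    n_cities: int = 24
    grid_size: int = 32
    pop_block: int = 4
    years: tuple[int, ...] = (2000, 2005, 2010, 2015, 2020)
    scenes_per_year: int = 8
    trend_mix: tuple[float, float, float] = (0.6, 0.1, 0.3)
    noise_sd: float = 0.02
    cloud_rate: float = 0.10
    water_rate: float = 0.05
    outlier_rate: float = 0.01
    adult_fraction: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.n_cities < 1:
            raise ValueError("n_cities must be >= 1")
        if self.grid_size < self.pop_block or self.pop_block < 1:
            raise ValueError("grid_size must be >= pop_block >= 1")
        if self.grid_size % self.pop_block != 0:
            raise ValueError("grid_size must be divisible by pop_block")
        if len(self.years) < 1 or list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be a non-empty increasing sequence")
        if self.scenes_per_year < 1:
            raise ValueError("scenes_per_year must be >= 1")
        if len(self.trend_mix) != 3 or abs(sum(self.trend_mix) - 1.0) > 1e-9 or any(
            f < 0 for f in self.trend_mix
        ):
            raise ValueError("trend_mix fractions must be non-negative and sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("cloud_rate", "water_rate", "outlier_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 <= self.adult_fraction <= 1.0):
            raise ValueError("adult_fraction must lie in [0, 1]")


@dataclass
class CityData:
    """One city's raster stack: scenes with QA flags, water, population."""

    city: City
    scenes: dict[int, list[tuple[RasterGrid, RasterGrid]]]
    water: RasterGrid
    population: dict[int, RasterGrid]
    outlier_positions: dict[tuple[int, int], np.ndarray]


@dataclass
class GroundTruth:
    """What the generator knows to be true, for parameter-recovery checks.

    ``ndvi``: city_id, year, true_ndvi (the exact annual exposure);
    ``trends``: city_id, true_slope, true_class;
    ``population``: city_id, year, total_population, adult_population
    (sums over the city's member coarse pixels);
    ``deaths``: per-city per-scenario attributable deaths under the
    central ERF, derived from the true exposures via the HIA equations.
    """

    ndvi: pd.DataFrame
    trends: pd.DataFrame
    population: pd.DataFrame
    deaths: pd.DataFrame


@dataclass
class StudyBundle:
    config: SyntheticConfig
    cities: list[City]
    city_data: dict[str, CityData]
    demographics: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Outlier injection
# ---------------------------------------------------------------------------


def inject_outliers(
    grid: RasterGrid, rate: float, rng: np.random.Generator | int
) -> tuple[RasterGrid, np.ndarray]:
    """Replace a fraction of valid pixels with out-of-range NDVI values.

    Exactly ``round(rate * n_valid)`` valid pixels are overwritten with
    values outside the plausible [-0.2, 1.0] range (half below, half
    above).  Returns the contaminated grid and the flat indices of the
    injected positions.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("outlier rate must lie in [0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    valid_idx = np.flatnonzero(grid.valid_mask().ravel())
    n = int(round(rate * valid_idx.size))
    if n == 0:
        return grid.with_values(grid.values.copy()), np.empty(0, dtype=np.intp)
    chosen = rng.choice(valid_idx, size=n, replace=False)
    low = rng.random(n) < 0.5
    vals = np.where(
        low,
        rng.uniform(-0.6, NDVI_MIN - 0.05, size=n),
        rng.uniform(NDVI_MAX + 0.05, 1.5, size=n),
    )
    flat = grid.values.copy().ravel()
    flat[chosen] = vals
    return grid.with_values(flat.reshape(grid.values.shape)), np.sort(chosen)


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


def _city_polygon(rng: np.random.Generator, x0: float, y0: float, size: int) -> Polygon:
    """Convex urban-extent polygon inside one city tile (with a margin)."""
    pts = rng.uniform(0.12 * size, 0.88 * size, size=(15, 2))
    hull = MultiPoint([(x0 + px, y0 + py) for px, py in pts]).convex_hull
    return Polygon(hull)


def _population_grid(
    rng: np.random.Generator,
    template: RasterGrid,
    polygon: Polygon,
    total_target: float,
    member: np.ndarray,
) -> np.ndarray:
    """Centre-periphery density surface scaled to a member-pixel total."""
    xx, yy = template.pixel_centres()
    cx, cy = polygon.centroid.x, polygon.centroid.y
    extent = template.width * template.pixel_size
    sigma = 0.30 * extent
    density = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    density *= rng.uniform(0.85, 1.15, size=density.shape)  # local texture
    inside = density[member].sum()
    return density * (total_target / inside)


def generate_study(config: SyntheticConfig) -> StudyBundle:
    """Generate the full synthetic study bundle (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.grid_size
    coarse = size // config.pop_block
    years = list(config.years)
    year0 = years[0]
    tiles_per_row = int(np.ceil(np.sqrt(config.n_cities)))
    tile_gap = size * 1.25  # keeps city polygons disjoint

    n_inc = int(round(config.trend_mix[0] * config.n_cities))
    n_dec = int(round(config.trend_mix[1] * config.n_cities))
    classes = (["Increase"] * n_inc + ["Decrease"] * n_dec
               + ["NoChange"] * (config.n_cities - n_inc - n_dec))[: config.n_cities]
    rng.shuffle(classes)

    cities: list[City] = []
    city_data: dict[str, CityData] = {}
    demo_rows, ndvi_rows, trend_rows, pop_rows = [], [], [], []

    for idx in range(config.n_cities):
        city_id = f"C{idx:03d}"
        tx = (idx % tiles_per_row) * tile_gap
        ty = (idx // tiles_per_row) * tile_gap
        region = _REGION_LIST[idx % len(_REGION_LIST)]
        province = f"P{idx // 3:02d}"
        coarse_tpl = RasterGrid(
            np.zeros((coarse, coarse)), tx, ty, float(config.pop_block),
            kind="population",
        )
        # redraw until the polygon captures at least one coarse pixel centre
        for _ in range(50):
            polygon = _city_polygon(rng, tx, ty, size)
            city = City(city_id, f"City {idx}", province, region, polygon)
            coarse_member = rasterize_city_mask(city, coarse_tpl).values == 1.0
            if coarse_member.any():
                break
        else:  # pragma: no cover - vanishingly unlikely at supported sizes
            raise RuntimeError(f"could not place a polygon for {city_id}")
        cities.append(city)

        # --- true NDVI trajectory: linear in year, uniform in space -------
        klass = classes[idx]
        if klass == "Increase":
            slope = rng.uniform(0.001, 0.006)
        elif klass == "Decrease":
            slope = -rng.uniform(0.001, 0.006)
        else:
            slope = 0.0
        span = years[-1] - year0
        lo = 0.18 + max(0.0, -slope) * span
        hi = 0.62 - max(0.0, slope) * span
        base = rng.uniform(lo, hi)
        true_ndvi = {yr: base + slope * (yr - year0) for yr in years}
        trend_rows.append(
            {"city_id": city_id, "true_slope": slope, "true_class": klass}
        )

        # --- water mask (fine grid, constant across years) ----------------
        water_vals = (rng.random((size, size)) < config.water_rate).astype(float)
        water = RasterGrid(water_vals, tx, ty, 1.0, kind="water_mask")

        # --- population grids ----------------------------------------------
        base_pop = 10 ** rng.uniform(4.7, 6.3)  # ~50k to ~2M residents
        growth = rng.uniform(0.0, 0.03)
        population: dict[int, RasterGrid] = {}
        for yr in years:
            target = base_pop * (1.0 + growth) ** (yr - year0)
            vals = _population_grid(rng, coarse_tpl, polygon, target, coarse_member)
            grid = RasterGrid(
                vals, tx, ty, float(config.pop_block), year=yr, kind="population"
            )
            population[yr] = grid
            total = float(vals[coarse_member].sum())
            pop_rows.append(
                {
                    "city_id": city_id,
                    "year": yr,
                    "total_population": total,
                    "adult_population": total * config.adult_fraction,
                }
            )
            demo_rows.append(
                {
                    "city_id": city_id,
                    "year": yr,
                    "adult_fraction": config.adult_fraction,
                    "y0": _y0_for_year(yr),
                }
            )

        # --- NDVI scene stacks ---------------------------------------------
        months = np.linspace(1, 12, config.scenes_per_year)
        months = np.round(months).astype(int)
        scenes: dict[int, list[tuple[RasterGrid, RasterGrid]]] = {}
        outlier_positions: dict[tuple[int, int], np.ndarray] = {}
        for yr in years:
            ndvi_rows.append(
                {"city_id": city_id, "year": yr, "true_ndvi": true_ndvi[yr]}
            )
            year_scenes = []
            for s in range(config.scenes_per_year):
                vals = np.full((size, size), true_ndvi[yr])
                if config.noise_sd > 0:
                    vals = vals + rng.normal(0.0, config.noise_sd, size=(size, size))
                scene = RasterGrid(
                    vals, tx, ty, 1.0, year=yr, month=int(months[s]),
                    kind="ndvi_scene",
                )
                scene, positions = inject_outliers(scene, config.outlier_rate, rng)
                outlier_positions[(yr, s)] = positions
                qa_vals = (rng.random((size, size)) >= config.cloud_rate).astype(float)
                qa = RasterGrid(qa_vals, tx, ty, 1.0, year=yr, kind="qa_flag")
                year_scenes.append((scene, qa))
            scenes[yr] = year_scenes

        city_data[city_id] = CityData(city, scenes, water, population,
                                      outlier_positions)

    demographics = pd.DataFrame(demo_rows)
    truth_ndvi = pd.DataFrame(ndvi_rows)
    truth_pop = pd.DataFrame(pop_rows)
    deaths = _true_deaths(truth_ndvi, truth_pop, demographics, years)
    ground_truth = GroundTruth(
        ndvi=truth_ndvi,
        trends=pd.DataFrame(trend_rows),
        population=truth_pop,
        deaths=deaths,
    )
    return StudyBundle(config, cities, city_data, demographics, ground_truth)


def _true_deaths(
    truth_ndvi: pd.DataFrame,
    truth_pop: pd.DataFrame,
    demographics: pd.DataFrame,
    years: list[int],
) -> pd.DataFrame:
    """Attributable deaths implied by the true exposures, via the HIA core."""
    exposures = truth_ndvi.merge(truth_pop, on=["city_id", "year"])
    exposures = exposures.rename(columns={"true_ndvi": "weighted_ndvi"})
    scenarios = [
        s for s in hia.SCENARIOS
        if all(y in years for y in hia.SCENARIO_SPECS[s][1])
    ]
    return hia.run_hia(exposures, demographics, hia.ERF(), scenarios)


# ---------------------------------------------------------------------------
# On-disk bundle layout (External Interfaces)
# ---------------------------------------------------------------------------


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Materialise a bundle: grids, GeoJSON cities, CSV tables, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cities(bundle.cities, out / "cities.geojson")
    write_demographics(bundle.demographics, out / "demographics.csv")
    bundle.ground_truth.ndvi.to_csv(out / "truth_ndvi.csv", index=False)
    bundle.ground_truth.trends.to_csv(out / "truth_trends.csv", index=False)
    bundle.ground_truth.population.to_csv(out / "truth_population.csv", index=False)
    bundle.ground_truth.deaths.to_csv(out / "truth_deaths.csv", index=False)
    cfg = bundle.config
    write_keyvalue(
        {
            "n_cities": cfg.n_cities,
            "grid_size": cfg.grid_size,
            "pop_block": cfg.pop_block,
            "years": list(cfg.years),
            "scenes_per_year": cfg.scenes_per_year,
            "trend_mix": list(cfg.trend_mix),
            "noise_sd": cfg.noise_sd,
            "cloud_rate": cfg.cloud_rate,
            "water_rate": cfg.water_rate,
            "outlier_rate": cfg.outlier_rate,
            "adult_fraction": cfg.adult_fraction,
            "seed": cfg.seed,
        },
        out / "config.txt",
    )
    for city_id, data in bundle.city_data.items():
        cdir = out / "cities" / city_id
        cdir.mkdir(parents=True, exist_ok=True)
        write_raster(data.water, cdir / "water.grid")
        for yr, grid in data.population.items():
            write_raster(grid, cdir / f"population_{yr}.grid")
        for yr, year_scenes in data.scenes.items():
            for s, (scene, qa) in enumerate(year_scenes):
                write_raster(scene, cdir / f"ndvi_{yr}_{s:02d}.grid")
                write_raster(qa, cdir / f"qa_{yr}_{s:02d}.grid")


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a plain-text key=value config back into a SyntheticConfig."""
    raw = read_keyvalue(path)
    kwargs: dict = {}
    casts = {
        "n_cities": int, "grid_size": int, "pop_block": int,
        "scenes_per_year": int, "seed": int,
        "noise_sd": float, "cloud_rate": float, "water_rate": float,
        "outlier_rate": float, "adult_fraction": float,
    }
    for key, cast in casts.items():
        if key in raw:
            kwargs[key] = cast(raw[key])
    if "years" in raw:
        kwargs["years"] = tuple(int(v) for v in raw["years"].split(","))
    if "trend_mix" in raw:
        kwargs["trend_mix"] = tuple(float(v) for v in raw["trend_mix"].split(","))
    config = SyntheticConfig(**kwargs)
    config.validate()
    return config


def read_bundle(in_dir: str | Path) -> StudyBundle:
    """Load a bundle written by :func:`write_bundle`."""
    from .io_formats import read_cities, read_demographics, read_raster

    root = Path(in_dir)
    config = load_config(root / "config.txt")
    cities = read_cities(root / "cities.geojson")
    demographics = read_demographics(root / "demographics.csv")
    ground_truth = GroundTruth(
        ndvi=pd.read_csv(root / "truth_ndvi.csv", dtype={"city_id": str}),
        trends=pd.read_csv(root / "truth_trends.csv", dtype={"city_id": str}),
        population=pd.read_csv(root / "truth_population.csv", dtype={"city_id": str}),
        deaths=pd.read_csv(root / "truth_deaths.csv", dtype={"city_id": str}),
    )
    city_data: dict[str, CityData] = {}
    for city in cities:
        cdir = root / "cities" / city.city_id
        water = read_raster(cdir / "water.grid")
        population = {
            yr: read_raster(cdir / f"population_{yr}.grid") for yr in config.years
        }
        scenes: dict[int, list[tuple[RasterGrid, RasterGrid]]] = {}
        for yr in config.years:
            scenes[yr] = [
                (
                    read_raster(cdir / f"ndvi_{yr}_{s:02d}.grid"),
                    read_raster(cdir / f"qa_{yr}_{s:02d}.grid"),
                )
                for s in range(config.scenes_per_year)
            ]
        city_data[city.city_id] = CityData(city, scenes, water, population, {})
    return StudyBundle(config, cities, city_data, demographics, ground_truth)
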