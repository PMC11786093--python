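"""Typed readers and writers for every on-disk artifact.

Grids are stored as a self-describing plain-text format carrying the same
header fields a single-band GeoTIFF would (width, height, transform, nodata)
plus the survey-year and kind metadata the pipeline needs.  Geometry uses
planar coordinates: origin at the top-left corner, x increasing with column,
y increasing with row, row-major 0-based indices, half-open pixel extents
``[origin + i*size, origin + (i+1)*size)``.

City boundaries travel as GeoJSON FeatureCollections (RFC 7946) with the
properties ``city_id``, ``name``, ``province``, ``region`` and ``level``;
tables as UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

logger = logging.getLogger("greenhia")

#: The seven geographic regions every city must belong to.
REGIONS = frozenset(
    {
        "North China",
        "Northeast China",
        "East China",
        "Central China",
        "South China",
        "Southwest China",
        "Northwest China",
    }
)

GRID_KINDS = frozenset(
    {"ndvi_scene", "ndvi_composite", "population", "water_mask", "qa_flag"}
)

#: Default nodata sentinel for all float grids.
NODATA = -9999.0

_MAGIC = "GREENHIA-GRID 1"


class GridFormatError(ValueError):
    """Malformed grid file: bad header, dimension mismatch, unknown kind."""


class GridValidationError(ValueError):
    """Grid content violates the invariants of its kind."""


class CityParseError(ValueError):
    """A GeoJSON feature cannot be turned into a :class:`City`."""


# ---------------------------------------------------------------------------
# RasterGrid
# ---------------------------------------------------------------------------


@dataclass
class RasterGrid:
    """A single-band planar grid with transform and survey metadata.

    Parameters
    ----------
    values
        2-D float array.  NDVI grids are dimensionless (nominal [-1, 1]);
        population grids hold persons per cell (non-negative); mask grids
        hold {0, 1}.  ``nodata`` marks missing cells.
    origin_x, origin_y
        Planar coordinates of the top-left grid corner.
    pixel_size
        Cell edge length in planar units.
    nodata
        Missing-value sentinel.
    year, month
        Survey year and (for 16-day-style scenes) calendar month.
    kind
        One of :data:`GRID_KINDS`; drives validation.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 1.0
    nodata: float = NODATA
    year: int | None = None
    month: int | None = None
    kind: str = "ndvi_scene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise GridValidationError("grid values must be a non-empty 2-D array")
        if self.kind not in GRID_KINDS:
            raise GridFormatError(f"unknown grid kind {self.kind!r}")
        if self.pixel_size <= 0:
            raise GridValidationError("pixel_size must be positive")
        valid = self.valid_mask()
        if self.kind in ("water_mask", "qa_flag"):
            vals = self.values[valid]
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise GridValidationError(
                    f"{self.kind} grid must contain only 0, 1 or nodata"
                )
        elif self.kind == "population":
            vals = self.values[valid]
            if np.any(vals < 0):
                raise GridValidationError("population grid contains negative cells")

    # -- shape & masks ------------------------------------------------------

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Boolean array marking finite, non-nodata cells."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask().sum())

    # -- geometry -----------------------------------------------------------

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) planar coordinates of every cell centre, row-major."""
        cols = np.arange(self.width)
        rows = np.arange(self.height)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y + (rows + 0.5) * self.pixel_size
        xx, yy = np.meshgrid(x, y)
        return xx, yy

    def with_values(self, values: np.ndarray, *, kind: str | None = None) -> "RasterGrid":
        """Copy of this grid with new values (and optionally a new kind)."""
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       kind=self.kind if kind is None else kind)

    def same_shape(self, other: "RasterGrid") -> bool:
        return self.values.shape == other.values.shape


def require_coregistered(a: RasterGrid, b: RasterGrid, what: str = "grids") -> None:
    """Raise unless two grids share shape, origin and pixel size."""
    if not a.same_shape(b):
        raise GridValidationError(
            f"{what} shape mismatch: {a.values.shape} vs {b.values.shape}"
        )
    if (a.origin_x, a.origin_y, a.pixel_size) != (b.origin_x, b.origin_y, b.pixel_size):
        raise GridValidationError(f"{what} transform mismatch")


# ---------------------------------------------------------------------------
# Grid file format
# ---------------------------------------------------------------------------


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as plain text; round-trips values and metadata exactly."""
    path = Path(path)
    lines = [
        _MAGIC,
        f"width {grid.width}",
        f"height {grid.height}",
        f"origin_x {grid.origin_x!r}",
        f"origin_y {grid.origin_y!r}",
        f"pixel_size {grid.pixel_size!r}",
        f"nodata {grid.nodata!r}",
        f"year {'none' if grid.year is None else grid.year}",
        f"month {'none' if grid.month is None else grid.month}",
        f"kind {grid.kind}",
        "DATA",
    ]
    body = "\n".join(
        " ".join(format(v, ".17g") for v in row) for row in grid.values
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n", encoding="utf-8")


def read_raster(path: str | Path) -> RasterGrid:
    """Read a grid written by :func:`write_raster`.

    Raises :class:`GridFormatError` on a malformed header or a data block
    whose dimensions disagree with the header.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise GridFormatError(f"{path}: missing {_MAGIC!r} magic line")
    header: dict[str, str] = {}
    data_start = None
    for i, line in enumerate(lines[1:], start=1):
        if line.strip() == "DATA":
            data_start = i + 1
            break
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise GridFormatError(f"{path}: malformed header line {line!r}")
        header[parts[0]] = parts[1].strip()
    if data_start is None:
        raise GridFormatError(f"{path}: missing DATA section")
    try:
        width = int(header["width"])
        height = int(header["height"])
        origin_x = float(header["origin_x"])
        origin_y = float(header["origin_y"])
        pixel_size = float(header["pixel_size"])
        nodata = float(header["nodata"])
        year = None if header["year"] == "none" else int(header["year"])
        month = None if header["month"] == "none" else int(header["month"])
        kind = header["kind"]
    except (KeyError, ValueError) as exc:
        raise GridFormatError(f"{path}: bad header field ({exc})") from exc
    rows = [ln for ln in lines[data_start:] if ln.strip()]
    if len(rows) != height:
        raise GridFormatError(
            f"{path}: header says {height} rows, data block has {len(rows)}"
        )
    try:
        values = np.array([[float(v) for v in row.split()] for row in rows])
    except ValueError as exc:
        raise GridFormatError(f"{path}: non-numeric cell ({exc})") from exc
    if values.shape != (height, width):
        raise GridFormatError(
            f"{path}: data block shape {values.shape} != header ({height}, {width})"
        )
    grid = RasterGrid(values, origin_x, origin_y, pixel_size, nodata, year, month, kind)
    if grid.n_valid == 0:
        logger.warning("%s: grid has zero valid pixels", path)
    return grid


# ---------------------------------------------------------------------------
# Cities
# ---------------------------------------------------------------------------


@dataclass
class City:
    """A city (or province-level municipality) with its urban-extent polygon."""

    city_id: str
    name: str
    province: str
    region: str
    polygon: Polygon | MultiPolygon
    level: str = "city"  # "city" | "province_unit"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise CityParseError(
                f"city {self.city_id!r}: region {self.region!r} not one of the "
                f"seven geographic regions"
            )
        if self.level not in ("city", "province_unit"):
            raise CityParseError(f"city {self.city_id!r}: bad level {self.level!r}")
        # degenerate zero-area polygons pass here and yield an empty mask
        # downstream (with a warning); self-intersecting rings are rejected
        if not self.polygon.is_valid and self.polygon.area > 0:
            raise CityParseError(
                f"city {self.city_id!r}: polygon is invalid (self-intersecting?)"
            )


_REQUIRED_PROPS = ("city_id", "name", "province", "region")


def read_cities(path: str | Path) -> list[City]:
    """Parse a GeoJSON FeatureCollection into cities.

    Every feature must carry the properties ``city_id``, ``name``,
    ``province`` and ``region`` (one of the seven regions) and a Polygon or
    MultiPolygon geometry with closed, non-self-intersecting rings.  Errors
    name the offending feature index.
    """
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise CityParseError(f"{path}: not a GeoJSON FeatureCollection")
    features = doc.get("features", [])
    if not features:
        logger.warning("%s: empty FeatureCollection", path)
        return []
    cities: list[City] = []
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        for key in _REQUIRED_PROPS:
            if key not in props:
                raise CityParseError(f"feature {i}: missing property {key!r}")
        geom = feat.get("geometry")
        if geom is None or geom.get("type") not in ("Polygon", "MultiPolygon"):
            raise CityParseError(f"feature {i}: geometry must be (Multi)Polygon")
        for ring in _iter_rings(geom):
            if ring[0] != ring[-1]:
                raise CityParseError(f"feature {i}: ring is not closed")
        poly = shape(geom)
        try:
            cities.append(
                City(
                    city_id=str(props["city_id"]),
                    name=str(props["name"]),
                    province=str(props["province"]),
                    region=str(props["region"]),
                    polygon=poly,
                    level=str(props.get("level", "city")),
                )
            )
        except CityParseError as exc:
            raise CityParseError(f"feature {i}: {exc}") from exc
    return cities


def _iter_rings(geom: dict) -> Iterable[list]:
    if geom["type"] == "Polygon":
        yield from geom["coordinates"]
    else:
        for part in geom["coordinates"]:
            yield from part


def write_cities(cities: Sequence[City], path: str | Path) -> None:
    """Write cities as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(c.polygon),
            "properties": {
                "city_id": c.city_id,
                "name": c.name,
                "province": c.province,
                "region": c.region,
                "level": c.level,
            },
        }
        for c in cities
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicRecord:
    """Adult-population fraction and baseline mortality for one city-year."""

    city_id: str
    year: int
    adult_fraction: float
    y0: float  # annual all-cause mortality rate, deaths per person-year

    def __post_init__(self) -> None:
        if not (0.0 < self.y0 < 1.0):
            raise GridValidationError(
                f"{self.city_id}/{self.year}: y0 must lie in (0, 1), got {self.y0}"
            )
        if not (0.0 <= self.adult_fraction <= 1.0):
            raise GridValidationError(
                f"{self.city_id}/{self.year}: adult_fraction must lie in [0, 1]"
            )


DEMOGRAPHIC_COLUMNS = ["city_id", "year", "adult_fraction", "y0"]


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read and validate a demographic table (city_id, year, adult_fraction, y0)."""
    df = pd.read_csv(path, dtype={"city_id": str})
    missing = set(DEMOGRAPHIC_COLUMNS) - set(df.columns)
    if missing:
        raise GridFormatError(f"{path}: demographic table missing columns {missing}")
    for row in df.itertuples(index=False):
        DemographicRecord(str(row.city_id), int(row.year),
                          float(row.adult_fraction), float(row.y0))
    return df[DEMOGRAPHIC_COLUMNS]


def write_demographics(df: pd.DataFrame, path: str | Path) -> None:
    df[DEMOGRAPHIC_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------


def rasterize_city_mask(city: City, template: RasterGrid) -> RasterGrid:
    """Membership mask on the template grid by centre-point test.

    A pixel belongs to the city iff its centre lies strictly inside the
    polygon (the reproducible convention for per-pixel zonal sums).  Returns
    a grid of kind ``qa_flag`` holding {0, 1}.
    """
    xx, yy = template.pixel_centres()
    pts = shapely.points(xx.ravel(), yy.ravel())
    inside = shapely.contains(city.polygon, pts).reshape(template.values.shape)
    if not inside.any():
        logger.warning(
            "city %s: polygon yields an empty mask on the template grid",
            city.city_id,
        )
    mask = template.with_values(inside.astype(np.float64), kind="qa_flag")
    return mask


# ---------------------------------------------------------------------------
# Plain-text key=value config
# ---------------------------------------------------------------------------


def write_keyvalue(data: dict, path: str | Path) -> None:
    """Write a flat mapping as ``key = value`` lines (lists comma-joined)."""
    lines = []
    for key, value in data.items():
        if isinstance(value, (list, tuple)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_keyvalue(path: str | Path) -> dict[str, str]:
    """Read ``key = value`` lines; values stay strings, split on demand."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise GridFormatError(f"{path}: malformed config line {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
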