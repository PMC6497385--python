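"""Reading, validating and writing the external data formats.

Covers occurrence CSVs, ESRI ASCII-grid rasters, GeoJSON polygon sets,
Newick trees and the species attribute table, plus the equidistant
cylindrical projection used whenever metric distances or areas are needed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .tree import Tree, check_ultrametric

__all__ = [
    "GeoIOError",
    "OccurrenceTable",
    "RasterGrid",
    "PolygonSet",
    "SpeciesAttributes",
    "EquidistantProjection",
    "read_occurrences",
    "read_raster",
    "write_raster",
    "read_polygons",
    "read_tree",
    "read_attributes",
]

EARTH_RADIUS_M = 6_371_008.8

VALID_CATEGORIES = {"CR", "EN", "VU", "NT", "LC", "DD", "NA"}


class GeoIOError(ValueError):
    """Raised for malformed external data."""


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class EquidistantProjection:
    """Equidistant cylindrical projection centred on the study region.

    Meridian distances are exact; parallel distances are exact at the
    central latitude.  Adequate for country-scale metric work (distances,
    hull areas, polygon intersections) and trivially invertible.
    """

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_M

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        k = math.cos(math.radians(self.lat0)) * math.pi / 180.0 * self.radius
        x = (lon - self.lon0) * k
        y = (lat - self.lat0) * (math.pi / 180.0 * self.radius)
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = math.cos(math.radians(self.lat0)) * math.pi / 180.0 * self.radius
        lon = x / k + self.lon0
        lat = y / (math.pi / 180.0 * self.radius) + self.lat0
        return lon, lat

    @classmethod
    def centred_on(cls, lons, lats) -> "EquidistantProjection":
        return cls(float(np.mean(lons)), float(np.mean(lats)))


# --------------------------------------------------------------------------
# occurrences
# --------------------------------------------------------------------------
@dataclass
class OccurrenceTable:
    """Deduplicated point records (species, lon, lat [, date, source])."""

    records: pd.DataFrame
    n_duplicates_removed: int = 0

    def __post_init__(self):
        required = {"species", "lon", "lat"}
        missing = required - set(self.records.columns)
        if missing:
            raise GeoIOError(f"missing occurrence columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    @property
    def source_counts(self) -> pd.Series:
        if "source" in self.records.columns:
            return self.records["source"].value_counts()
        return pd.Series(dtype=int)

    def for_species(self, species: str) -> pd.DataFrame:
        return self.records[self.records["species"] == species]

    def dedup(self) -> "OccurrenceTable":
        before = len(self.records)
        deduped = self.records.drop_duplicates(
            subset=["species", "lon", "lat"], keep="first"
        ).reset_index(drop=True)
        return OccurrenceTable(
            deduped, self.n_duplicates_removed + before - len(deduped)
        )


def read_occurrences(path: str | Path, dedup: bool = True) -> OccurrenceTable:
    """Read an occurrence CSV (``species,lon,lat[,date,source]``).

    Exact duplicates on (species, lon, lat) are collapsed keeping the first
    record when ``dedup`` is true; out-of-range coordinates are reported
    with their line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise GeoIOError(f"{path}: empty occurrence file") from exc
    if df.empty:
        raise GeoIOError(f"{path}: no occurrence records")
    table = OccurrenceTable(df)

    problems = []
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = (
        lon.isna() | lat.isna()
        | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
        | df["species"].isna() | (df["species"].astype(str).str.strip() == "")
    )
    for idx in df.index[bad]:
        # +2: header line plus 1-based numbering
        problems.append(f"line {idx + 2}: {df.loc[idx].to_dict()}")
    if problems:
        raise GeoIOError(
            f"{path}: {len(problems)} malformed record(s):\n" + "\n".join(problems)
        )
    df = df.assign(lon=lon, lat=lat)
    table = OccurrenceTable(df)
    return table.dedup() if dedup else table


# --------------------------------------------------------------------------
# rasters
# --------------------------------------------------------------------------
@dataclass
class RasterGrid:
    """Regular raster; row 0 is the northernmost row.

    ``origin_x, origin_y`` locate the outer (north-west) corner of cell
    (0, 0); cell (r, c) spans the half-open box
    ``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]``.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0
    crs_tag: str = "wgs84-geographic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeoIOError("raster values must be a 2-D matrix")
        if not (math.isfinite(self.cell_size) and self.cell_size > 0):
            raise GeoIOError(f"invalid cell_size {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return (self.values != self.nodata) & np.isfinite(self.values)

    def cell_of(self, x, y):
        """(row, col) arrays for coordinates; no bounds check."""
        from .gridding import floor_snap

        col = floor_snap((np.asarray(x) - self.origin_x) / self.cell_size)
        row = floor_snap((self.origin_y - np.asarray(y)) / self.cell_size)
        return row, col

    def contains(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_centers(self):
        """(x, y) center-coordinate arrays shaped like ``values``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def like(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(
            self.origin_x, self.origin_y, self.cell_size,
            values, self.nodata, self.crs_tag,
        )


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GeoIOError(f"{path}: missing ASCII-grid header field {key}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    except Exception as exc:
        raise GeoIOError(f"{path}: malformed raster data: {exc}") from exc
    if values.shape != (n_rows, n_cols):
        raise GeoIOError(
            f"{path}: header promises {n_rows}x{n_cols}, data is {values.shape}"
        )
    cell = header["cellsize"]
    return RasterGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (value-identical round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# --------------------------------------------------------------------------
# polygons
# --------------------------------------------------------------------------
@dataclass
class PolygonSet:
    """Named polygons in a shared coordinate frame."""

    names: list[str]
    geometries: list[BaseGeometry]
    crs_tag: str = "wgs84-geographic"

    def __post_init__(self):
        if len(self.names) != len(self.geometries):
            raise GeoIOError("names and geometries differ in length")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.geometries))

    def union(self) -> BaseGeometry:
        from shapely.ops import unary_union

        return unary_union(self.geometries)

    def areas(self) -> dict[str, float]:
        return {n: g.area for n, g in self}

    def project(self, proj: EquidistantProjection) -> "PolygonSet":
        from shapely.ops import transform

        projected = [
            transform(lambda x, y: proj.forward(x, y), g) for g in self.geometries
        ]
        return PolygonSet(list(self.names), projected, "uae-equidistant-metres")


def read_polygons(path: str | Path) -> PolygonSet:
    """Read a GeoJSON FeatureCollection with a ``name`` property per feature."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise GeoIOError(f"{path}: expected a GeoJSON FeatureCollection")
    features = doc.get("features", [])
    if not features:
        warnings.warn(f"{path}: empty polygon collection", stacklevel=2)
        return PolygonSet([], [])
    names, geoms = [], []
    for i, feat in enumerate(features):
        geom = feat.get("geometry")
        if geom is None:
            raise GeoIOError(f"{path}: feature {i} has no geometry")
        for ring_set in _iter_rings(geom):
            for ring in ring_set:
                if len(ring) < 4 or ring[0] != ring[-1]:
                    raise GeoIOError(f"{path}: feature {i} has an unclosed ring")
        names.append(str(feat.get("properties", {}).get("name", f"feature-{i}")))
        geoms.append(shapely_shape(geom))
    return PolygonSet(names, geoms)


def _iter_rings(geom: dict):
    if geom["type"] == "Polygon":
        yield geom["coordinates"]
    elif geom["type"] == "MultiPolygon":
        yield from geom["coordinates"]
    else:
        raise GeoIOError(f"unsupported geometry type {geom['type']}")


def polygons_to_geojson(polys: PolygonSet, path: str | Path) -> None:
    from shapely.geometry import mapping

    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in polys
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# --------------------------------------------------------------------------
# trees & attributes
# --------------------------------------------------------------------------
def read_tree(path: str | Path, ultrametric_tol: float = 1e-6) -> Tree:
    """Parse a Newick tree; warn (not fail) if it is not ultrametric."""
    tree = Tree.from_newick(Path(path).read_text())
    check_ultrametric(tree, ultrametric_tol)
    return tree


@dataclass
class SpeciesAttributes:
    """Per-species traits: national category, native/venomous flags, group."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"species", "national_category", "native", "venomous"}
        missing = required - set(self.table.columns)
        if missing:
            raise GeoIOError(f"missing attribute columns: {sorted(missing)}")
        bad = set(self.table["national_category"]) - VALID_CATEGORIES
        if bad:
            raise GeoIOError(f"unknown national category code(s): {sorted(bad)}")
        intro = self.table[~self.table["native"].astype(bool)]
        if not (intro["national_category"] == "NA").all():
            raise GeoIOError("introduced species must carry category NA")
        self.table = self.table.set_index("species", drop=False)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def species(self) -> list[str]:
        return list(self.table["species"])

    def native_species(self) -> list[str]:
        return list(self.table.loc[self.table["native"].astype(bool), "species"])

    def venomous_species(self) -> list[str]:
        return list(self.table.loc[self.table["venomous"].astype(bool), "species"])

    def threatened_species(self) -> list[str]:
        flag = self.table["national_category"].isin({"CR", "EN", "VU"})
        return list(self.table.loc[flag, "species"])

    def category_counts(self) -> pd.Series:
        return self.table["national_category"].value_counts()

    def check_covers(self, occurrences: OccurrenceTable) -> None:
        missing = set(occurrences.species) - set(self.species)
        if missing:
            raise GeoIOError(f"species missing from attribute table: {sorted(missing)}")


def read_attributes(path: str | Path) -> SpeciesAttributes:
    # keep_default_na: the national category "NA" (Not Applicable) is a code
    return SpeciesAttributes(pd.read_csv(path, keep_default_na=False))
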