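"""Analysis grids, occupancy, richness maps, convex hulls and region tallies.

The atlas grid is anchored at integer multiples of the cell size from the
global origin (0 deg E, 0 deg N), so grids built over different extents share
cell indices for shared cells.  Cell membership uses a half-open rule with
the west and north edges inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, Point
from shapely.prepared import prep

from .geoio import OccurrenceTable, PolygonSet, RasterGrid

__all__ = [
    "GridSpec",
    "CellMetricMap",
    "ConvexPolygon",
    "DegenerateHullError",
    "OutOfGridError",
    "build_grid",
    "assign_cell",
    "occupancy",
    "richness_map",
    "sampled_fraction",
    "region_mask",
    "minimum_convex_polygon",
    "tally_by_region",
]

ARCMIN10 = 10.0 / 60.0  # atlas resolution in degrees


def floor_snap(q):
    """Floor that first snaps values numerically indistinguishable from an
    integer (1e-12 relative) onto it, so points on cell edges assign
    identically across grids whose anchors were snapped independently."""
    q = np.asarray(q, dtype=float)
    r = np.round(q)
    on_edge = np.abs(q - r) <= 1e-12 * np.maximum(1.0, np.abs(q))
    return np.where(on_edge, r, np.floor(q)).astype(int)


class OutOfGridError(ValueError):
    """Point falls outside the grid extent."""


class DegenerateHullError(ValueError):
    """Fewer than three non-collinear points; caller decides the fallback."""


@dataclass(frozen=True)
class GridSpec:
    """Regular grid; ``(x0, y0)`` is the outer NW corner of cell (0, 0)."""

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_tag: str = "wgs84-geographic"

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_box(self, row: int, col: int):
        s = self.cell_size
        return box(
            self.x0 + col * s, self.y0 - (row + 1) * s,
            self.x0 + (col + 1) * s, self.y0 - row * s,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.cell_size
        return self.x0 + (col + 0.5) * s, self.y0 - (row + 0.5) * s

    def assign(self, x, y):
        """Vectorised cell assignment; west/north edges inclusive.

        A point exactly on an interior edge belongs to the cell whose
        west/north edge it sits on (half-open convention)."""
        col = floor_snap((np.asarray(x, float) - self.x0) / self.cell_size)
        row = floor_snap((self.y0 - np.asarray(y, float)) / self.cell_size)
        return row, col

    def contains(self, row, col):
        row, col = np.asarray(row), np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float,
    crs_tag: str = "wgs84-geographic",
) -> GridSpec:
    """Grid covering *extent* ``(xmin, xmax, ymin, ymax)``.

    The anchor snaps outward to integer multiples of ``cell_size`` from the
    global origin, so overlapping grids align cell-for-cell.
    """
    xmin, xmax, ymin, ymax = extent
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent")
    eps = 1e-9 * cell_size
    x0 = np.floor(xmin / cell_size + eps) * cell_size
    y0 = np.ceil(ymax / cell_size - eps) * cell_size
    n_cols = int(np.ceil((xmax - x0) / cell_size - eps))
    n_rows = int(np.ceil((y0 - ymin) / cell_size - eps))
    return GridSpec(x0, y0, cell_size, n_rows, n_cols, crs_tag)


def assign_cell(x: float, y: float, grid: GridSpec) -> tuple[int, int]:
    """Cell index of a single point; raises :class:`OutOfGridError` outside."""
    row, col = grid.assign(x, y)
    if not grid.contains(row, col):
        raise OutOfGridError(f"point ({x}, {y}) outside grid extent")
    return int(row), int(col)


# --------------------------------------------------------------------------
# occupancy & richness
# --------------------------------------------------------------------------
def occupancy(
    table: OccurrenceTable, grid: GridSpec, strict: bool = False
) -> dict[str, set[tuple[int, int]]]:
    """Per-species sets of occupied cells.

    Records outside the grid are dropped (or raise when ``strict``).
    Invariant under record order and duplicate injection.
    """
    df = table.records
    row, col = grid.assign(df["lon"].to_numpy(), df["lat"].to_numpy())
    inside = grid.contains(row, col)
    if strict and not inside.all():
        raise OutOfGridError(f"{(~inside).sum()} record(s) outside the grid")
    occ: dict[str, set[tuple[int, int]]] = {}
    for sp, r, c, ok in zip(df["species"], row, col, inside):
        if ok:
            occ.setdefault(sp, set()).add((int(r), int(c)))
    return occ


@dataclass
class CellMetricMap:
    """Values keyed by (row, col) cell indices of a :class:`GridSpec`."""

    grid: GridSpec
    values: dict[tuple[int, int], float]
    semantics: str = "count"

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (r, c), v in sorted(self.values.items()):
            cx, cy = self.grid.cell_center(r, c)
            rows.append({"row": r, "col": c, "center_lon": cx,
                         "center_lat": cy, "value": v})
        return pd.DataFrame(rows, columns=["row", "col", "center_lon",
                                           "center_lat", "value"])

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_raster(self, nodata: float = -9999.0) -> RasterGrid:
        vals = np.full((self.grid.n_rows, self.grid.n_cols), nodata)
        for (r, c), v in self.values.items():
            vals[r, c] = v
        return RasterGrid(self.grid.x0, self.grid.y0, self.grid.cell_size,
                          vals, nodata, self.grid.crs_tag)


def richness_map(
    occ: dict[str, set[tuple[int, int]]],
    grid: GridSpec,
    species: set[str] | None = None,
) -> CellMetricMap:
    """Number of (selected) species occupying each cell.

    ``species`` filters to a subset (native-only, venomous-only, ...);
    ``None`` counts all species in the occupancy set.
    """
    values: dict[tuple[int, int], float] = {}
    for sp, cells in occ.items():
        if species is not None and sp not in species:
            continue
        for cell in cells:
            values[cell] = values.get(cell, 0) + 1
    return CellMetricMap(grid, values, "richness")


def region_mask(
    grid: GridSpec, region: PolygonSet | "object"
) -> set[tuple[int, int]]:
    """Cells intersecting the region polygon(s) with positive area."""
    geom = region.union() if isinstance(region, PolygonSet) else region
    prepared = prep(geom)
    mask: set[tuple[int, int]] = set()
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            cell = grid.cell_box(r, c)
            if prepared.intersects(cell) and geom.intersection(cell).area > 0:
                mask.add((r, c))
    return mask


def sampled_fraction(
    occ: dict[str, set[tuple[int, int]]],
    grid: GridSpec,
    mask: set[tuple[int, int]],
) -> float:
    """(#cells with at least one record) / (#cells in the region mask)."""
    if not mask:
        raise ValueError("empty region mask")
    occupied: set[tuple[int, int]] = set()
    for cells in occ.values():
        occupied |= cells
    return len(occupied & mask) / len(mask)


# --------------------------------------------------------------------------
# convex hulls
# --------------------------------------------------------------------------
@dataclass
class ConvexPolygon:
    """Convex hull with counter-clockwise vertices (metric coordinates)."""

    vertices: np.ndarray

    @property
    def area(self) -> float:
        # shoelace formula
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def to_shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)


def minimum_convex_polygon(points: np.ndarray) -> ConvexPolygon:
    """Convex hull by Andrew's monotone chain; CCW vertex order.

    Raises :class:`DegenerateHullError` for fewer than three points or an
    all-collinear configuration.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        raise DegenerateHullError(f"need >=3 distinct points, got {len(pts)}")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise DegenerateHullError("all points collinear")
    return ConvexPolygon(hull)


# --------------------------------------------------------------------------
# regional tallies
# --------------------------------------------------------------------------
def tally_by_region(
    table: OccurrenceTable, regions: PolygonSet
) -> pd.DataFrame:
    """Species presence counts per named region.

    A species counts in a region when at least one record falls inside its
    polygon; points on shared borders go to the first-listed region.
    Records in no region land in an ``unassigned`` bucket.
    """
    prepared = [(name, prep(geom), geom) for name, geom in regions]
    membership: dict[str, set[str]] = {name: set() for name, _ in regions}
    membership["unassigned"] = set()
    for sp, lon, lat in zip(
        table.records["species"], table.records["lon"], table.records["lat"]
    ):
        pt = Point(lon, lat)
        for name, pgeom, geom in prepared:
            if pgeom.intersects(pt):  # covers boundary: first-listed wins
                membership[name].add(sp)
                break
        else:
            membership["unassigned"].add(sp)
    return pd.DataFrame(
        {"region": list(membership), "n_species": [len(v) for v in membership.values()],
         "species": [sorted(v) for v in membership.values()]}
    )
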