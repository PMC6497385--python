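"""Protected-area gap analysis: AOO, SPD and coverage targets.

Distribution areas are expressed in 2 x 2 km (4 km^2) cells of a metric
fine grid.  The area of occupancy (AOO) counts the unique cells holding
records; the species potential distribution (SPD) counts the fine cells
whose center falls inside the modelled binary range, or inside the minimum
convex polygon of the records for species with too few presences to model.
Protected fractions use exact polygon intersections between the union of a
species' cells and the union of the protected-area polygons, and are then
compared with the 17% (Aichi) and relaxed 12% coverage targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .geoio import PolygonSet
from .gridding import DegenerateHullError, GridSpec, minimum_convex_polygon
from .sdm import BinaryRange

__all__ = [
    "TargetConfig",
    "aoo",
    "aoo_cells",
    "spd_from_sdm",
    "spd_from_mcp",
    "protected_fraction",
    "classify_targets",
    "summarize_protection",
    "CELL_AREA_KM2",
]

CELL_AREA_KM2 = 4.0  # one 2 x 2 km fine cell


@dataclass(frozen=True)
class TargetConfig:
    """Coverage thresholds as percentages of a species' area."""

    strict: float = 17.0
    relaxed: float = 12.0

    def __post_init__(self):
        for t in (self.strict, self.relaxed):
            if not (0 < t < 100):
                raise ValueError(f"threshold {t} outside (0, 100)")


# --------------------------------------------------------------------------
# areas
# --------------------------------------------------------------------------
def aoo_cells(x, y, fine_grid: GridSpec) -> set[tuple[int, int]]:
    """Unique fine cells occupied by records (metric coordinates)."""
    row, col = fine_grid.assign(np.asarray(x), np.asarray(y))
    inside = fine_grid.contains(row, col)
    return {(int(r), int(c)) for r, c, ok in zip(
        np.atleast_1d(row), np.atleast_1d(col), np.atleast_1d(inside)) if ok}


def aoo(x, y, fine_grid: GridSpec) -> float:
    """Area of occupancy: unique occupied 2x2 km cells x 4 km^2."""
    return len(aoo_cells(x, y, fine_grid)) * CELL_AREA_KM2


def spd_cells_from_sdm(
    binary: BinaryRange, fine_grid: GridSpec, to_raster_frame=None
) -> set[tuple[int, int]]:
    """Fine cells whose center samples a TRUE pixel of the binary range.

    ``to_raster_frame`` maps fine-grid center coordinates into the binary
    raster's frame (e.g. metric back to geographic) and defaults to the
    identity when both share a frame.
    """
    grid = binary.grid
    rows = np.repeat(np.arange(fine_grid.n_rows), fine_grid.n_cols)
    cols = np.tile(np.arange(fine_grid.n_cols), fine_grid.n_rows)
    cx = fine_grid.x0 + (cols + 0.5) * fine_grid.cell_size
    cy = fine_grid.y0 - (rows + 0.5) * fine_grid.cell_size
    if to_raster_frame is not None:
        cx, cy = to_raster_frame(cx, cy)
    pr, pc = grid.cell_of(cx, cy)
    ok = grid.contains(pr, pc)
    hit = np.zeros(len(rows), dtype=bool)
    hit[ok] = binary.mask[pr[ok], pc[ok]]
    return {(int(r), int(c)) for r, c in zip(rows[hit], cols[hit])}


def spd_from_sdm(
    binary: BinaryRange, fine_grid: GridSpec, to_raster_frame=None
) -> float:
    """SPD area from a modelled binary range, by center sampling."""
    return len(spd_cells_from_sdm(binary, fine_grid, to_raster_frame)) \
        * CELL_AREA_KM2


def spd_cells_from_mcp(x, y, fine_grid: GridSpec) -> set[tuple[int, int]]:
    """Fine cells whose center lies inside (or on) the records' convex hull.

    Degenerate hulls (fewer than three non-collinear points) fall back to
    the cells containing the records themselves.
    """
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    try:
        hull = minimum_convex_polygon(np.column_stack([x, y])).to_shapely()
    except DegenerateHullError:
        return aoo_cells(x, y, fine_grid)
    from shapely.geometry import Point
    from shapely.prepared import prep

    prepared = prep(hull)
    cells = set()
    minx, miny, maxx, maxy = hull.bounds
    r0, c0 = fine_grid.assign(minx, maxy)
    r1, c1 = fine_grid.assign(maxx, miny)
    for r in range(max(0, int(r0) - 1), min(fine_grid.n_rows, int(r1) + 2)):
        for c in range(max(0, int(c0) - 1), min(fine_grid.n_cols, int(c1) + 2)):
            cx, cy = fine_grid.cell_center(r, c)
            if prepared.intersects(Point(cx, cy)):  # boundary counts as inside
                cells.add((r, c))
    return cells


def spd_from_mcp(x, y, fine_grid: GridSpec) -> float:
    return len(spd_cells_from_mcp(x, y, fine_grid)) * CELL_AREA_KM2


# --------------------------------------------------------------------------
# protection
# --------------------------------------------------------------------------
def protected_fraction(
    cells: set[tuple[int, int]],
    fine_grid: GridSpec,
    protected: PolygonSet,
) -> float:
    """Percent of the cell-union area inside the protected polygons.

    Exact geometric intersection (partially covered cells count pro rata);
    cells and polygons must share the metric frame.
    """
    if not cells:
        raise ValueError("protected fraction undefined for an empty cell set")
    cell_union = unary_union([fine_grid.cell_box(r, c) for r, c in cells])
    pa_union = protected.union()
    if pa_union.is_empty:
        return 0.0
    inter = cell_union.intersection(pa_union).area
    return 100.0 * inter / cell_union.area


def classify_targets(
    percent: float, cfg: TargetConfig = TargetConfig()
) -> dict[str, bool]:
    """Meets-17 / meets-12 booleans and a no-overlap flag."""
    return {
        "meets_strict": percent >= cfg.strict,
        "meets_relaxed": percent >= cfg.relaxed,
        "no_overlap": percent == 0.0,
    }


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------
def summarize_protection(
    table: pd.DataFrame,
    native: set[str] | None = None,
    cfg: TargetConfig = TargetConfig(),
) -> pd.DataFrame:
    """Counts/percentages below each target per approach, over native species.

    ``table`` needs columns ``species``, ``pct_AOO_protected`` and
    ``pct_SPD_protected``; introduced species are excluded from all summary
    conclusions when ``native`` is given.
    """
    df = table if native is None else table[table["species"].isin(native)]
    n = len(df)
    if n == 0:
        raise ValueError("no species to summarize")
    rows = []
    for approach in ("AOO", "SPD"):
        pct = df[f"pct_{approach}_protected"].to_numpy(dtype=float)
        below_strict = int((pct < cfg.strict).sum())
        below_relaxed = int((pct < cfg.relaxed).sum())
        rows.append({
            "approach": approach,
            "n_species": n,
            "n_below_strict": below_strict,
            "pct_below_strict": 100.0 * below_strict / n,
            "n_below_relaxed": below_relaxed,
            "pct_below_relaxed": 100.0 * below_relaxed / n,
            "mean_protected_pct": float(pct.mean()),
            "pct_any_overlap": 100.0 * float((pct > 0).sum()) / n,
        })
    return pd.DataFrame(rows)


def gap_analysis_report(
    species_records: dict[str, tuple[np.ndarray, np.ndarray]],
    binary_ranges: dict[str, BinaryRange],
    fine_grid: GridSpec,
    protected: PolygonSet,
    attributes: pd.DataFrame | None = None,
    cfg: TargetConfig = TargetConfig(),
    to_raster_frame=None,
) -> pd.DataFrame:
    """Per-species AOO/SPD areas, protected fractions and target status.

    Species absent from ``binary_ranges`` use the convex-hull fallback for
    their SPD.  AOO > SPD is possible (records outside the modelled range);
    it is checked and logged, not asserted away.
    """
    rows = []
    for sp, (x, y) in sorted(species_records.items()):
        cells_aoo = aoo_cells(x, y, fine_grid)
        if sp in binary_ranges:
            cells_spd = spd_cells_from_sdm(binary_ranges[sp], fine_grid,
                                           to_raster_frame)
            method = "sdm"
        else:
            cells_spd = spd_cells_from_mcp(x, y, fine_grid)
            method = "mcp"
        area_aoo = len(cells_aoo) * CELL_AREA_KM2
        area_spd = len(cells_spd) * CELL_AREA_KM2
        if area_aoo > area_spd:
            warnings.warn(f"{sp}: AOO ({area_aoo}) exceeds SPD ({area_spd})",
                          stacklevel=2)
        pct_aoo = protected_fraction(cells_aoo, fine_grid, protected)
        pct_spd = protected_fraction(cells_spd, fine_grid, protected)
        st_aoo = classify_targets(pct_aoo, cfg)
        st_spd = classify_targets(pct_spd, cfg)
        row = {
            "species": sp,
            "spd_method": method,
            "AOO_km2": area_aoo,
            "SPD_km2": area_spd,
            "pct_AOO_protected": pct_aoo,
            "pct_SPD_protected": pct_spd,
            "meets17_AOO": st_aoo["meets_strict"],
            "meets12_AOO": st_aoo["meets_relaxed"],
            "meets17_SPD": st_spd["meets_strict"],
            "meets12_SPD": st_spd["meets_relaxed"],
            "any_overlap": pct_aoo > 0 or pct_spd > 0,
        }
        if attributes is not None and sp in set(attributes["species"]):
            row["category"] = attributes.set_index("species").loc[
                sp, "national_category"]
        rows.append(row)
    return pd.DataFrame(rows)
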