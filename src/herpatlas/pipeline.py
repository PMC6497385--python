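"""Pipeline driver: ingest -> grids -> climate space -> SDM -> PD/ED -> gap
-> reports, with one master seed and per-stage derived seeds.

The configuration is a flat key-value mapping; every analysis constant
(10 arc-minute atlas cells, 2-km fine cells, 5 pseudo-absences per
presence, 500-m altitude split, 100 replicates, 25% test fraction, 0.01
learning rate, 2,000 iterations, 4 hidden units, 10,000 null draws,
17%/12% targets, 48/96-my ED cutoffs) is a default that can be overridden.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate_space as cs
from . import gap_analysis as gap
from . import gridding, phylodiversity as phylo, sdm
from .geoio import (
    EquidistantProjection,
    read_attributes,
    read_occurrences,
    read_polygons,
    read_raster,
    read_tree,
    write_raster,
)

__all__ = ["PipelineConfig", "run_pipeline", "parse_config"]

DEFAULTS = dict(
    atlas_cell_deg=10.0 / 60.0,
    fine_cell_m=2000.0,
    pa_ratio=5,
    altitude_split_m=500.0,
    sdm_replicates=100,
    sdm_test_fraction=0.25,
    sdm_learning_rate=0.01,
    sdm_iterations=2000,
    sdm_hidden_units=4,
    sdm_min_presences=5,
    null_draws=10000,
    target_strict_pct=17.0,
    target_relaxed_pct=12.0,
    seed=0,
)


@dataclass
class PipelineConfig:
    occurrences: str
    tree: str
    attributes: str
    rasters_dir: str
    protected_areas: str
    regions: str
    out_dir: str
    atlas_cell_deg: float = DEFAULTS["atlas_cell_deg"]
    fine_cell_m: float = DEFAULTS["fine_cell_m"]
    pa_ratio: int = DEFAULTS["pa_ratio"]
    altitude_split_m: float = DEFAULTS["altitude_split_m"]
    sdm_replicates: int = DEFAULTS["sdm_replicates"]
    sdm_test_fraction: float = DEFAULTS["sdm_test_fraction"]
    sdm_learning_rate: float = DEFAULTS["sdm_learning_rate"]
    sdm_iterations: int = DEFAULTS["sdm_iterations"]
    sdm_hidden_units: int = DEFAULTS["sdm_hidden_units"]
    sdm_min_presences: int = DEFAULTS["sdm_min_presences"]
    null_draws: int = DEFAULTS["null_draws"]
    target_strict_pct: float = DEFAULTS["target_strict_pct"]
    target_relaxed_pct: float = DEFAULTS["target_relaxed_pct"]
    seed: int = DEFAULTS["seed"]


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    kwargs: dict = {}
    for key, val in values.items():
        default = DEFAULTS.get(key)
        if isinstance(default, float):
            kwargs[key] = float(val)
        elif isinstance(default, int):
            kwargs[key] = int(val)
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write versioned CSV / ASCII-grid outputs.

    Identical configuration and seed give byte-identical CSV outputs.
    Returns a dict of the in-memory artifacts for programmatic use.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed = {cfg.seed}"]
    artifacts: dict = {"config": asdict(cfg)}

    # ---------------------------------------------------------- ingest
    @_stage("ingest")
    def ingest():
        occ = read_occurrences(cfg.occurrences, dedup=True)
        attrs = read_attributes(cfg.attributes)
        attrs.check_covers(occ)
        tree = read_tree(cfg.tree)
        pas = read_polygons(cfg.protected_areas)
        regions = read_polygons(cfg.regions)
        rasters = {
            p.stem: read_raster(p)
            for p in sorted(Path(cfg.rasters_dir).glob("*.asc"))
        }
        if "BIO1" not in rasters or "BIO12" not in rasters:
            raise ValueError("rasters_dir must provide BIO1 and BIO12")
        return occ, attrs, tree, pas, regions, rasters

    occ, attrs, tree, pas, regions, rasters = ingest()
    log_lines.append(f"ingest: {len(occ)} records, {len(attrs)} species, "
                     f"{len(pas)} protected areas")

    # ---------------------------------------------------------- grids
    @_stage("grids")
    def grids():
        bio1 = rasters["BIO1"]
        extent = (bio1.origin_x, bio1.origin_x + bio1.n_cols * bio1.cell_size,
                  bio1.origin_y - bio1.n_rows * bio1.cell_size, bio1.origin_y)
        atlas = gridding.build_grid(extent, cfg.atlas_cell_deg)
        occ_cells = gridding.occupancy(occ, atlas)
        native = set(attrs.native_species())
        maps = {
            "richness_all": gridding.richness_map(occ_cells, atlas),
            "richness_native": gridding.richness_map(occ_cells, atlas, native),
            "richness_venomous": gridding.richness_map(
                occ_cells, atlas, set(attrs.venomous_species())),
            "richness_threatened": gridding.richness_map(
                occ_cells, atlas, set(attrs.threatened_species())),
        }
        mask = gridding.region_mask(atlas, regions)
        frac = gridding.sampled_fraction(occ_cells, atlas, mask)
        tally = gridding.tally_by_region(occ, regions)
        return atlas, occ_cells, maps, mask, frac, tally

    atlas, occ_cells, rich_maps, mask, sampled_frac, tally = grids()
    for name, m in rich_maps.items():
        m.write_csv(out / f"{name}.csv")
        write_raster(m.to_raster(), out / f"{name}.asc")
    tally.to_csv(out / "richness_by_region.csv", index=False)
    log_lines.append(f"grids: {len(mask)} atlas cells in mask, "
                     f"sampled fraction {sampled_frac:.4f}")

    # ---------------------------------------------------------- climate space
    @_stage("climate")
    def climate():
        bio = {f"BIO{i}": rasters[f"BIO{i}"] for i in range(1, 20)
               if f"BIO{i}" in rasters}
        matrix = cs.ClimateMatrix.from_rasters(bio)
        pca = cs.pca_climate(matrix)
        part = cs.delimit_clusters(pca)
        px_km2 = _pixel_area_km2(rasters["BIO1"])
        stats = cs.cluster_stats(part, matrix, occ, px_km2)
        return matrix, pca, part, stats

    matrix, pca, partition, clus_stats = climate()
    clus_stats.to_csv(out / "cluster_stats.csv", index=False)
    pd.DataFrame({"component": np.arange(1, len(pca.explained) + 1),
                  "explained_fraction": pca.explained}).to_csv(
        out / "pca_explained.csv", index=False)
    log_lines.append(f"climate: {partition.n_clusters} clusters from "
                     f"{partition.n_bands} bands")

    # ---------------------------------------------------------- SDM
    proj = _projection_for(rasters["BIO1"])

    @_stage("sdm")
    def run_sdm():
        predictors = _predictor_stack(rasters)
        dem = rasters["DEM"]
        valid = np.ones(dem.values.shape, dtype=bool)
        for g in predictors.values():
            valid &= g.valid_mask
        ranges: dict[str, sdm.BinaryRange] = {}
        auc_rows = []
        for i, sp in enumerate(sorted(occ.species)):
            recs = occ.for_species(sp)
            pres = sdm.presence_pixels(recs["lon"].to_numpy(),
                                       recs["lat"].to_numpy(),
                                       next(iter(predictors.values())))
            if not sdm.eligible_for_sdm(pres, cfg.sdm_min_presences):
                auc_rows.append({"species": sp, "n_presence_pixels": len(pres),
                                 "auc_mean": np.nan, "auc_sd": np.nan,
                                 "method": "mcp"})
                continue
            pa_cfg = sdm.PseudoAbsenceConfig(
                cfg.pa_ratio, cfg.altitude_split_m, cfg.seed * 1000 + i)
            absences = sdm.sample_pseudo_absences(pres, dem, valid.copy(), pa_cfg)
            net_cfg = sdm.NetConfig(
                cfg.sdm_hidden_units, cfg.sdm_learning_rate,
                cfg.sdm_iterations, 5, cfg.sdm_replicates,
                cfg.sdm_test_fraction, cfg.seed * 1000 + i + 1)
            ens = sdm.fit_ensemble(predictors, pres, absences, net_cfg)
            rng_binary = sdm.contiguity_filter(
                sdm.threshold_binary(ens.mean_raster, pres), pres)
            ranges[sp] = rng_binary
            auc_rows.append({"species": sp, "n_presence_pixels": len(pres),
                             "auc_mean": ens.auc_mean, "auc_sd": ens.auc_sd,
                             "method": "sdm"})
        return ranges, pd.DataFrame(auc_rows)

    binary_ranges, auc_report = run_sdm()
    auc_report.to_csv(out / "sdm_auc.csv", index=False)
    log_lines.append(f"sdm: {len(binary_ranges)} species modelled, "
                     f"{len(occ.species) - len(binary_ranges)} routed to MCP")

    # ---------------------------------------------------------- PD / ED
    @_stage("phylodiversity")
    def phylodiv():
        native = [s for s in attrs.native_species() if s in set(occ.species)]
        pruned = phylo.prune_tree(tree, native)
        native_occ = {s: c for s, c in occ_cells.items() if s in set(native)}
        pdmap = phylo.pd_map(native_occ, pruned, atlas)
        sdm_occ = _ranges_to_atlas_cells(binary_ranges, atlas, native)
        pdmap_sdm = phylo.pd_map(sdm_occ, pruned, atlas) if sdm_occ else None
        index = phylo.PhyloIndex(pruned)
        ses_rows = []
        by_cell: dict[tuple[int, int], set[str]] = {}
        for sp, cells in native_occ.items():
            for cell in cells:
                by_cell.setdefault(cell, set()).add(sp)
        for j, (cell, spset) in enumerate(sorted(by_cell.items())):
            ncfg = phylo.NullModelConfig(cfg.null_draws, cfg.seed * 4000 + j)
            ses, p, flag = phylo.pd_ses(index, spset, native, ncfg)
            ses_rows.append({"row": cell[0], "col": cell[1],
                             "pd": pdmap.values[cell], "ses": ses, "p": p,
                             "significant": flag})
        ed = phylo.fair_proportion_ed(pruned)
        edmap = phylo.ed_map(native_occ, ed, atlas)
        richness_native = gridding.richness_map(native_occ, atlas)
        r = phylo.pd_richness_correlation(pdmap, richness_native)
        return pdmap, pdmap_sdm, pd.DataFrame(ses_rows), ed, edmap, r

    pdmap, pdmap_sdm, ses_table, ed_table, edmap, pd_r = phylodiv()
    pdmap.write_csv(out / "pd_points.csv")
    if pdmap_sdm is not None:
        pdmap_sdm.write_csv(out / "pd_sdm.csv")
    ses_table.to_csv(out / "pd_ses.csv", index=False)
    ed_table.to_csv(out / "ed_species.csv", index=False)
    edmap.write_csv(out / "ed_cells.csv")
    log_lines.append(f"phylodiversity: PD-richness r = {pd_r:.4f}")

    # ---------------------------------------------------------- gap
    @_stage("gap")
    def gap_stage():
        native = set(attrs.native_species())
        pas_m = pas.project(proj)
        xs, ys = proj.forward(occ.records["lon"].to_numpy(),
                              occ.records["lat"].to_numpy())
        extent_m = (xs.min() - 5 * cfg.fine_cell_m, xs.max() + 5 * cfg.fine_cell_m,
                    ys.min() - 5 * cfg.fine_cell_m, ys.max() + 5 * cfg.fine_cell_m)
        fine = gridding.build_grid(extent_m, cfg.fine_cell_m,
                                   "uae-equidistant-metres")
        records_m = {}
        for sp in occ.species:
            recs = occ.for_species(sp)
            x, y = proj.forward(recs["lon"].to_numpy(), recs["lat"].to_numpy())
            records_m[sp] = (x, y)
        tcfg = gap.TargetConfig(cfg.target_strict_pct, cfg.target_relaxed_pct)
        report = gap.gap_analysis_report(
            records_m, binary_ranges, fine, pas_m, attrs.table, tcfg,
            to_raster_frame=proj.inverse)
        summary = gap.summarize_protection(report, native, tcfg)
        return report, summary

    gap_report, gap_summary = gap_stage()
    gap_report.to_csv(out / "gap_report.csv", index=False)
    gap_summary.to_csv(out / "gap_summary.csv", index=False)

    # ---------------------------------------------------------- reports
    from .reporting import checklist_stats

    checklist = checklist_stats(attrs)
    checklist.to_csv(out / "checklist_stats.csv", index=False)
    pd.DataFrame([{"sampled_fraction": sampled_frac,
                   "pd_richness_r": pd_r}]).to_csv(
        out / "headline.csv", index=False)
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")

    artifacts.update(
        occurrences=occ, attributes=attrs, tree=tree, atlas=atlas,
        occupancy=occ_cells, richness_maps=rich_maps,
        sampled_fraction=sampled_frac, pca=pca, partition=partition,
        cluster_stats=clus_stats, binary_ranges=binary_ranges,
        auc_report=auc_report, pd_map=pdmap, pd_map_sdm=pdmap_sdm,
        pd_ses=ses_table, ed_table=ed_table, ed_map=edmap,
        pd_richness_r=pd_r, gap_report=gap_report, gap_summary=gap_summary,
        checklist=checklist,
    )
    return artifacts


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------
def _projection_for(grid) -> EquidistantProjection:
    lon0 = grid.origin_x + grid.n_cols * grid.cell_size / 2
    lat0 = grid.origin_y - grid.n_rows * grid.cell_size / 2
    return EquidistantProjection(lon0, lat0)


def _pixel_area_km2(grid) -> float:
    proj = _projection_for(grid)
    x0, y0 = proj.forward(grid.origin_x, grid.origin_y - grid.n_rows
                          * grid.cell_size / 2)
    x1, y1 = proj.forward(grid.origin_x + grid.cell_size,
                          grid.origin_y - grid.n_rows * grid.cell_size / 2
                          - grid.cell_size)
    return abs((x1 - x0) * (y0 - y1)) / 1e6


def _predictor_stack(rasters: dict) -> dict:
    """The four-variable SDM stack: NDVI components plus BIO1 and BIO12."""
    stack = {}
    if "NDVI_C1" in rasters and "NDVI_C2" in rasters:
        stack["ndvi_c1"] = rasters["NDVI_C1"]
        stack["ndvi_c2"] = rasters["NDVI_C2"]
    else:
        series_files = sorted(
            k for k in rasters if k.startswith("NDVI_") and k[5:].isdigit())
        if not series_files:
            raise ValueError("no NDVI components or series rasters found")
        first = rasters[series_files[0]]
        series = np.stack([rasters[k].values for k in series_files])
        flat = series.reshape(len(series_files), -1)
        c1, c2 = sdm.ndvi_harmonics(flat, period=len(series_files))
        stack["ndvi_c1"] = first.like(c1.reshape(first.values.shape))
        stack["ndvi_c2"] = first.like(c2.reshape(first.values.shape))
    stack["BIO1"] = rasters["BIO1"]
    stack["BIO12"] = rasters["BIO12"]
    return stack


def _ranges_to_atlas_cells(binary_ranges: dict, atlas, native: list
                           ) -> dict[str, set[tuple[int, int]]]:
    """Atlas-cell occupancy implied by binary SDM ranges (pixel centers)."""
    out: dict[str, set[tuple[int, int]]] = {}
    for sp, br in binary_ranges.items():
        if sp not in set(native):
            continue
        g = br.grid
        rc = np.argwhere(br.mask)
        if len(rc) == 0:
            continue
        lon = g.origin_x + (rc[:, 1] + 0.5) * g.cell_size
        lat = g.origin_y - (rc[:, 0] + 0.5) * g.cell_size
        row, col = atlas.assign(lon, lat)
        ok = atlas.contains(row, col)
        out[sp] = {(int(r), int(c)) for r, c in zip(row[ok], col[ok])}
    return out
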