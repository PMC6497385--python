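"""Climatic-space PCA, variance-quota clusters and species ecological profiles.

The multivariate climatic space is the standardized 19-variable bioclim
matrix over all valid pixels.  Clusters are axis-parallel bands along PC1
and PC2: each component contributes ceil(explained_fraction / quota) bands,
with band edges placed so every band carries an equal share of the
component's squared scores.  The partition is the Cartesian product of the
two band sets, with empty combinations dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geoio import OccurrenceTable, RasterGrid

__all__ = [
    "ClimateMatrix",
    "PCAResult",
    "ClusterPartition",
    "SpeciesProfile",
    "pca_climate",
    "delimit_clusters",
    "cluster_stats",
    "species_profile",
]


@dataclass
class ClimateMatrix:
    """Pixels x variables climate matrix with the pixel -> cell mapping."""

    values: np.ndarray            # (n_pixels, n_vars), no nodata rows
    columns: list[str]            # variable names, fixed order
    pixel_rc: np.ndarray          # (n_pixels, 2) row/col in the source grid
    grid: RasterGrid | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values shape does not match column names")
        if not np.isfinite(self.values).all():
            raise ValueError("climate matrix contains nodata/non-finite rows")

    @classmethod
    def from_rasters(cls, layers: dict[str, RasterGrid]) -> "ClimateMatrix":
        names = list(layers)
        first = layers[names[0]]
        mask = np.ones(first.values.shape, dtype=bool)
        for g in layers.values():
            if g.values.shape != first.values.shape:
                raise ValueError("climate layers are not co-registered")
            mask &= g.valid_mask
        rc = np.argwhere(mask)
        values = np.column_stack([layers[n].values[mask] for n in names])
        return cls(values, names, rc, first)

    def pixel_index(self) -> dict[tuple[int, int], int]:
        return {(int(r), int(c)): i for i, (r, c) in enumerate(self.pixel_rc)}


@dataclass
class PCAResult:
    loadings: np.ndarray            # (n_vars, k)
    scores: np.ndarray              # (n_pixels, k)
    eigenvalues: np.ndarray
    explained: np.ndarray           # fractions, non-increasing
    mean: np.ndarray
    scale: np.ndarray
    columns: list[str] = field(default_factory=list)


def pca_climate(matrix: ClimateMatrix) -> PCAResult:
    """PCA of the standardized climate matrix (correlation-matrix PCA).

    Columns are centred and scaled to unit variance before decomposition
    (bioclim variables carry incommensurate units).  The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 pixels for a PCA")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    constant = scale == 0
    if constant.all():
        raise ValueError("constant climate matrix")
    if constant.any():
        import warnings

        warnings.warn(
            f"zero-variance column(s) dropped from scaling: "
            f"{[matrix.columns[i] for i in np.where(constant)[0]]}",
            stacklevel=2,
        )
    safe_scale = np.where(constant, 1.0, scale)
    Z = (X - mean) / safe_scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s ** 2 / (X.shape[0] - 1)
    loadings = Vt.T
    scores = Z @ loadings
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    explained = eig / eig.sum()
    return PCAResult(loadings, scores, eig, explained, mean, safe_scale,
                     list(matrix.columns))


@dataclass
class ClusterPartition:
    """Axis-parallel climatic clusters over PC1/PC2 scores."""

    labels: np.ndarray                 # cluster id per pixel, contiguous from 1
    cuts_pc1: np.ndarray               # interior cut positions along PC1
    cuts_pc2: np.ndarray
    n_bands: tuple[int, int]
    band_pairs: list[tuple[int, int]]  # (band1, band2) per cluster id - 1

    @property
    def n_clusters(self) -> int:
        return len(self.band_pairs)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters + 1)[1:]


def _band_assign(scores: np.ndarray, n_bands: int) -> tuple[np.ndarray, np.ndarray]:
    """Band index per pixel so each band carries ~1/n_bands of sum(score^2).

    Edges are score values at the cumulative squared-score crossings; ties
    in score share a band, making the assignment pixel-order invariant.
    """
    if n_bands <= 1:
        return np.zeros(len(scores), dtype=int), np.array([])
    order = np.argsort(scores, kind="stable")
    w = scores[order] ** 2
    cw = np.cumsum(w)
    total = cw[-1]
    targets = total * np.arange(1, n_bands) / n_bands
    idx = np.searchsorted(cw, targets * (1 - 1e-12), side="left")
    cuts = scores[order][np.clip(idx, 0, len(scores) - 1)]
    # scores equal to a cut belong to the band below it
    bands = np.searchsorted(cuts, scores, side="left")
    return bands, cuts


def delimit_clusters(pca: PCAResult, quota: float = 0.20) -> ClusterPartition:
    """Partition PC1/PC2 score space into variance-quota clusters.

    Bands per axis = ceil(component's explained fraction / quota); clusters
    are non-empty band combinations renumbered by pixel count descending.
    """
    if not (0 < quota <= 1):
        raise ValueError(f"quota must be in (0, 1], got {quota}")
    if pca.scores.shape[1] < 2:
        raise ValueError("need at least 2 principal components")
    nb1 = int(np.ceil(pca.explained[0] / quota - 1e-12))
    nb2 = int(np.ceil(pca.explained[1] / quota - 1e-12))
    b1, cuts1 = _band_assign(pca.scores[:, 0], nb1)
    b2, cuts2 = _band_assign(pca.scores[:, 1], nb2)
    combo = b1 * nb2 + b2
    pairs, inverse, counts = np.unique(combo, return_inverse=True,
                                       return_counts=True)
    # renumber by area (pixel count) descending; ties by band order
    rank = np.lexsort((pairs, -counts))
    relabel = np.empty(len(pairs), dtype=int)
    relabel[rank] = np.arange(1, len(pairs) + 1)
    labels = relabel[inverse]
    band_pairs = [
        (int(pairs[r] // nb2), int(pairs[r] % nb2)) for r in rank
    ]
    return ClusterPartition(labels, cuts1, cuts2, (nb1, nb2), band_pairs)


def cluster_stats(
    partition: ClusterPartition,
    matrix: ClimateMatrix,
    occ: OccurrenceTable,
    pixel_area_km2: float,
) -> pd.DataFrame:
    """Per-cluster species counts, observations, %% sampled and area.

    ``% sampled`` is the fraction of the cluster's pixels holding at least
    one record.  Records falling on nodata pixels are excluded (logged via
    the returned ``n_excluded`` attribute column is not needed; a warning
    is emitted instead).
    """
    if matrix.grid is None:
        raise ValueError("climate matrix lacks its source grid")
    index = matrix.pixel_index()
    grid = matrix.grid
    row, col = grid.cell_of(occ.records["lon"].to_numpy(),
                            occ.records["lat"].to_numpy())
    pix = []
    n_excluded = 0
    for r, c in zip(row, col):
        key = (int(r), int(c))
        if key in index:
            pix.append(index[key])
        else:
            n_excluded += 1
    if n_excluded:
        import warnings

        warnings.warn(f"{n_excluded} record(s) on nodata pixels excluded",
                      stacklevel=2)
    pix = np.array(pix, dtype=int)
    # align species with the records retained on valid pixels
    valid_keys = np.array(
        [(int(r), int(c)) in index for r, c in zip(row, col)], dtype=bool)
    species = occ.records["species"].to_numpy()[valid_keys]

    rows = []
    for cid in range(1, partition.n_clusters + 1):
        members = partition.labels == cid
        n_pix = int(members.sum())
        rec_in = np.isin(pix, np.where(members)[0]) if len(pix) else np.array([], bool)
        n_obs = int(rec_in.sum())
        n_sp = len(set(species[rec_in])) if n_obs else 0
        occupied = len(set(pix[rec_in])) if n_obs else 0
        rows.append({
            "cluster": cid,
            "n_species": n_sp,
            "n_observations": n_obs,
            "pct_sampled": 100.0 * occupied / n_pix if n_pix else 0.0,
            "area_km2": n_pix * pixel_area_km2,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ecological profiles
# --------------------------------------------------------------------------
@dataclass
class SpeciesProfile:
    species: str
    elevation_histogram: dict[int, int]      # bin k covers [100k, 100(k+1)) m
    bio1: np.ndarray                         # per-record annual mean temp
    bio12: np.ndarray                        # per-record annual precipitation
    landcover_distances: pd.DataFrame        # class x (min, q1, median, q3, max)


def _distance_to_class(landcover: RasterGrid, cls: float,
                       pixel_size_m: float) -> np.ndarray | None:
    """Metric distance of every pixel to the nearest pixel of a class."""
    hits = landcover.values == cls
    if not hits.any():
        return None
    # EDT measures distance to the nearest zero of the input
    return ndimage.distance_transform_edt(~hits) * pixel_size_m


def species_profile(
    species: str,
    occ: OccurrenceTable,
    dem: RasterGrid,
    bio1: RasterGrid,
    bio12: RasterGrid,
    landcover: RasterGrid,
    landcover_classes: dict[str, float],
    pixel_size_m: float,
) -> SpeciesProfile:
    """Elevation histogram (100-m half-open bins), climate values and
    per-land-cover-class distance quartiles for one species' records.

    All rasters must be co-registered.  Classes absent from the raster get
    missing (NaN) distances.
    """
    recs = occ.for_species(species)
    lon = recs["lon"].to_numpy()
    lat = recs["lat"].to_numpy()

    def sample(grid: RasterGrid) -> np.ndarray:
        r, c = grid.cell_of(lon, lat)
        ok = grid.contains(r, c)
        out = np.full(len(lon), np.nan)
        out[ok] = grid.values[r[ok], c[ok]]
        out[out == grid.nodata] = np.nan
        return out

    elev = sample(dem)
    hist: dict[int, int] = {}
    for e in elev[np.isfinite(elev)]:
        k = int(np.floor(e / 100.0))
        hist[k] = hist.get(k, 0) + 1

    rows = []
    r, c = landcover.cell_of(lon, lat)
    ok = landcover.contains(r, c)
    for name, code in landcover_classes.items():
        dist = _distance_to_class(landcover, code, pixel_size_m)
        if dist is None:
            rows.append({"class": name, "min": np.nan, "q1": np.nan,
                         "median": np.nan, "q3": np.nan, "max": np.nan})
            continue
        d = np.full(len(lon), np.nan)
        d[ok] = dist[r[ok], c[ok]]
        d = d[np.isfinite(d)]
        if len(d) == 0:
            rows.append({"class": name, "min": np.nan, "q1": np.nan,
                         "median": np.nan, "q3": np.nan, "max": np.nan})
        else:
            q = np.percentile(d, [0, 25, 50, 75, 100])
            rows.append({"class": name, "min": q[0], "q1": q[1],
                         "median": q[2], "q3": q[3], "max": q[4]})
    return SpeciesProfile(
        species, hist, sample(bio1), sample(bio12), pd.DataFrame(rows)
    )
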