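"""Presence-only species distribution models.

The classifier is a deliberately small feed-forward network: one hidden
layer of four logistic units and a logistic output, trained by full-batch
gradient descent on the cross-entropy loss at a fixed learning rate.
Presences are opposed to randomly drawn pseudo-absences (five per presence,
balanced across two altitude classes), an ensemble of replicates with 75/25
train/test splits is fitted, replicate suitabilities are averaged, the
ensemble is thresholded at the lowest value predicted at any presence, and
only range components contiguous with a presence are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .geoio import RasterGrid

__all__ = [
    "PseudoAbsenceConfig",
    "NetConfig",
    "MLPClassifier",
    "EnsemblePrediction",
    "BinaryRange",
    "ndvi_harmonics",
    "eligible_for_sdm",
    "presence_pixels",
    "sample_pseudo_absences",
    "train_net",
    "auc",
    "fit_ensemble",
    "threshold_binary",
    "contiguity_filter",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class PseudoAbsenceConfig:
    """Pseudo-absence sampling: ratio per presence and the altitude split."""

    ratio: int = 5
    altitude_split: float = 500.0  # metres
    seed: int = 0

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError("pseudo-absence ratio must be >= 1")


@dataclass(frozen=True)
class NetConfig:
    """Network hyperparameters (heuristic values used for every species)."""

    hidden_units: int = 4
    learning_rate: float = 0.01
    iterations: int = 2000
    burn_in: int = 5
    replicates: int = 100
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.hidden_units, self.iterations, self.replicates) <= 0:
            raise ValueError("hidden_units, iterations, replicates must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")


# --------------------------------------------------------------------------
# NDVI harmonic summary
# --------------------------------------------------------------------------
def ndvi_harmonics(series: np.ndarray, period: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-component harmonic summary of a vegetation-index time series.

    Least-squares fit of ``y_t = a0 + a1 cos(2 pi t / period) +
    b1 sin(2 pi t / period)``; component 1 is the mean level ``a0`` and
    component 2 the annual amplitude ``sqrt(a1^2 + b1^2)`` (phase-free).

    ``series`` may be 1-D (one pixel) or 2-D ``(n_samples, n_pixels)``.
    All-missing pixels yield NaN in both components.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n = y.shape[0]
    if n < period:
        raise ValueError("need at least one full period of samples")
    t = np.arange(n)
    X = np.column_stack([
        np.ones(n),
        np.cos(2 * np.pi * t / period),
        np.sin(2 * np.pi * t / period),
    ])
    c1 = np.full(y.shape[1], np.nan)
    c2 = np.full(y.shape[1], np.nan)
    finite = np.isfinite(y)
    complete = finite.all(axis=0)
    if complete.any():
        coef, *_ = np.linalg.lstsq(X, y[:, complete], rcond=None)
        c1[complete] = coef[0]
        c2[complete] = np.hypot(coef[1], coef[2])
    # pixels with some (not all) missing samples: fit individually
    partial = ~complete & finite.any(axis=0)
    for j in np.where(partial)[0]:
        m = finite[:, j]
        if m.sum() >= 3:
            coef, *_ = np.linalg.lstsq(X[m], y[m, j], rcond=None)
            c1[j] = coef[0]
            c2[j] = np.hypot(coef[1], coef[2])
    if squeeze:
        return float(c1[0]), float(c2[0])
    return c1, c2


# --------------------------------------------------------------------------
# presences & pseudo-absences
# --------------------------------------------------------------------------
def presence_pixels(lon, lat, grid: RasterGrid) -> set[tuple[int, int]]:
    """Unique valid pixels holding at least one record."""
    r, c = grid.cell_of(np.asarray(lon), np.asarray(lat))
    ok = grid.contains(r, c)
    valid = grid.valid_mask
    return {
        (int(ri), int(ci))
        for ri, ci, k in zip(np.atleast_1d(r), np.atleast_1d(c), np.atleast_1d(ok))
        if k and valid[int(ri), int(ci)]
    }


def eligible_for_sdm(presences: set[tuple[int, int]], minimum: int = 5) -> bool:
    """Model a species only with >= 5 duplicate-free presence pixels;
    otherwise it is routed to the convex-hull fallback."""
    return len(presences) >= minimum


def sample_pseudo_absences(
    presences: set[tuple[int, int]],
    dem: RasterGrid,
    valid_mask: np.ndarray,
    cfg: PseudoAbsenceConfig,
) -> set[tuple[int, int]]:
    """Draw ``ratio * n`` background pixels, balanced across altitude classes.

    Half the quota (rounded up) comes from below ``altitude_split`` and half
    from at or above it; a class with too few candidate pixels hands its
    deficit to the other class.  Pseudo-absences never coincide with the
    species' own presence pixels.  Seeded and reproducible.
    """
    n_target = cfg.ratio * len(presences)
    candidates = valid_mask & dem.valid_mask
    for (r, c) in presences:
        candidates[r, c] = False
    rc = np.argwhere(candidates)
    if len(rc) == 0:
        raise ValueError("no candidate pixels for pseudo-absences")
    elev = dem.values[rc[:, 0], rc[:, 1]]
    low = rc[elev < cfg.altitude_split]
    high = rc[elev >= cfg.altitude_split]
    want_low = int(np.ceil(n_target / 2))
    want_high = n_target - want_low
    if len(low) < want_low:
        short = want_low - len(low)
        want_low = len(low)
        want_high += short
        warnings.warn(f"low-altitude class short by {short}; reallocated",
                      stacklevel=2)
    if len(high) < want_high:
        short = want_high - len(high)
        want_high = len(high)
        want_low = min(want_low + short, len(low))
        warnings.warn(f"high-altitude class short by {short}; reallocated",
                      stacklevel=2)
    if want_low + want_high < n_target:
        warnings.warn(
            f"only {want_low + want_high} candidate pixels for "
            f"{n_target} pseudo-absences; sampling all", stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    picks = []
    if want_low:
        picks.append(low[rng.choice(len(low), size=want_low, replace=False)])
    if want_high:
        picks.append(high[rng.choice(len(high), size=want_high, replace=False)])
    chosen = np.vstack(picks) if picks else np.empty((0, 2), dtype=int)
    return {(int(r), int(c)) for r, c in chosen}


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------
def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPClassifier:
    """One hidden layer of logistic units with a logistic output."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    feature_mean: np.ndarray
    feature_std: np.ndarray
    loss_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.feature_mean) / self.feature_std
        H = _sigmoid(Z @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2).ravel()


def train_net(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: NetConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> MLPClassifier:
    """Train the network by full-batch gradient descent on cross-entropy.

    Features are standardized with training-set statistics; initial weights
    are uniform in [-0.5, 0.5] from the seed, so identical seed/config/data
    give bit-identical weights.  The first ``burn_in`` recorded loss
    evaluations are discarded from the stored trace (they do not affect the
    final weights).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_in, n_h = Z.shape[1], cfg.hidden_units
    W1 = rng.uniform(-0.5, 0.5, size=(n_in, n_h))
    b1 = rng.uniform(-0.5, 0.5, size=n_h)
    W2 = rng.uniform(-0.5, 0.5, size=(n_h, 1))
    b2 = rng.uniform(-0.5, 0.5, size=1)

    losses = []
    for _ in range(cfg.iterations):
        H = _sigmoid(Z @ W1 + b1)
        p = _sigmoid(H @ W2 + b2).ravel()
        eps = 1e-12
        losses.append(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        # backprop of summed cross-entropy through the logistic output
        # (classical batch backprop; the 0.01 rate applies to the summed
        # gradient, which keeps convergence independent of sample count)
        delta_out = (p - y)[:, None]
        gW2 = H.T @ delta_out
        gb2 = delta_out.sum(axis=0)
        delta_h = (delta_out @ W2.T) * H * (1 - H)
        gW1 = Z.T @ delta_h
        gb1 = delta_h.sum(axis=0)
        W1 -= cfg.learning_rate * gW1
        b1 -= cfg.learning_rate * gb1
        W2 -= cfg.learning_rate * gW2
        b2 -= cfg.learning_rate * gb2
    trace = np.array(losses[cfg.burn_in:])
    return MLPClassifier(W1, b1, W2, b2, mean, std, trace)


# --------------------------------------------------------------------------
# AUC
# --------------------------------------------------------------------------
def auc(scores_presence: np.ndarray, scores_absence: np.ndarray) -> float:
    """Area under the ROC curve by the rank-sum formulation; ties count 1/2."""
    pos = np.asarray(scores_presence, dtype=float).ravel()
    neg = np.asarray(scores_absence, dtype=float).ravel()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


# --------------------------------------------------------------------------
# ensemble
# --------------------------------------------------------------------------
@dataclass
class EnsemblePrediction:
    mean_raster: RasterGrid
    replicate_auc: np.ndarray
    auc_mean: float
    auc_sd: float
    replicate_rasters: list[RasterGrid] | None = None


def _stack_features(
    predictors: dict[str, RasterGrid], pixels: np.ndarray
) -> np.ndarray:
    return np.column_stack(
        [g.values[pixels[:, 0], pixels[:, 1]] for g in predictors.values()]
    )


def _split(idx: np.ndarray, test_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(idx)
    n_test = max(1, int(round(test_fraction * len(idx))))
    return perm[n_test:], perm[:n_test]


def fit_ensemble(
    predictors: dict[str, RasterGrid],
    presences: set[tuple[int, int]],
    pseudo_absences: set[tuple[int, int]],
    cfg: NetConfig,
    keep_replicates: bool = False,
) -> EnsemblePrediction:
    """Replicated train/test ensemble over presences and pseudo-absences.

    Each replicate draws a stratified 75/25 split (presences and
    pseudo-absences split separately), trains the network, scores AUC on
    the held-out quarter and predicts suitability for all valid pixels; the
    ensemble reports the mean suitability raster and AUC mean +/- sd.
    """
    first = next(iter(predictors.values()))
    valid = np.ones(first.values.shape, dtype=bool)
    for g in predictors.values():
        valid &= g.valid_mask
    pres = np.array(sorted(presences))
    absn = np.array(sorted(pseudo_absences))
    Xp = _stack_features(predictors, pres)
    Xa = _stack_features(predictors, absn)
    X = np.vstack([Xp, Xa])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xa))])

    all_pix = np.argwhere(valid)
    Xall = _stack_features(predictors, all_pix)

    master = np.random.SeedSequence(cfg.seed)
    rep_seeds = master.spawn(cfg.replicates)
    mean_pred = np.zeros(len(all_pix))
    aucs = np.empty(cfg.replicates)
    reps: list[RasterGrid] = []
    for i, ss in enumerate(rep_seeds):
        rng = np.random.default_rng(ss)
        for attempt in range(10):
            tr_p, te_p = _split(np.arange(len(Xp)), cfg.test_fraction, rng)
            tr_a, te_a = _split(len(Xp) + np.arange(len(Xa)), cfg.test_fraction, rng)
            train = np.concatenate([tr_p, tr_a])
            test = np.concatenate([te_p, te_a])
            if len(np.unique(y[train])) == 2 and len(np.unique(y[test])) == 2:
                break
            warnings.warn(f"replicate {i}: degenerate split, resampling",
                          stacklevel=2)
        net = train_net(X[train], y[train], cfg, seed=rng)
        scores = net.predict(X[test])
        aucs[i] = auc(scores[y[test] == 1], scores[y[test] == 0])
        pred = net.predict(Xall)
        mean_pred += pred
        if keep_replicates:
            vals = np.full(first.values.shape, first.nodata)
            vals[all_pix[:, 0], all_pix[:, 1]] = pred
            reps.append(first.like(vals))
    mean_pred /= cfg.replicates
    vals = np.full(first.values.shape, first.nodata)
    vals[all_pix[:, 0], all_pix[:, 1]] = mean_pred
    return EnsemblePrediction(
        first.like(vals), aucs, float(aucs.mean()),
        float(aucs.std(ddof=1)) if cfg.replicates > 1 else 0.0,
        reps if keep_replicates else None,
    )


# --------------------------------------------------------------------------
# binary range
# --------------------------------------------------------------------------
@dataclass
class BinaryRange:
    mask: np.ndarray                 # boolean raster
    threshold: float
    grid: RasterGrid
    n_components_retained: int = 0

    def to_raster(self) -> RasterGrid:
        return self.grid.like(self.mask.astype(float))


def threshold_binary(
    mean_raster: RasterGrid, presences: set[tuple[int, int]]
) -> BinaryRange:
    """Binary range at the minimum-training-presence threshold.

    tau = smallest mean suitability at any presence pixel; pixels with
    suitability >= tau (inclusive, so every presence stays inside) are TRUE.
    """
    pres = np.array(sorted(presences))
    vals = mean_raster.values
    pvals = vals[pres[:, 0], pres[:, 1]]
    if not np.isfinite(pvals).all() or (pvals == mean_raster.nodata).any():
        raise ValueError("presence pixel without a prediction")
    tau = float(pvals.min())
    mask = mean_raster.valid_mask & (vals >= tau)
    return BinaryRange(mask, tau, mean_raster)


def contiguity_filter(
    binary: BinaryRange, presences: set[tuple[int, int]]
) -> BinaryRange:
    """Retain only range components containing a presence (8-neighbour)."""
    structure = np.ones((3, 3), dtype=int)  # diagonal touch counts
    labelled, n = ndimage.label(binary.mask, structure=structure)
    pres = np.array(sorted(presences))
    pres_labels = labelled[pres[:, 0], pres[:, 1]]
    assert (pres_labels > 0).all(), "presence pixel outside the binary range"
    keep = np.unique(pres_labels)
    mask = np.isin(labelled, keep)
    return BinaryRange(mask, binary.threshold, binary.grid, len(keep))
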