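"""Faith's phylogenetic diversity, its standardized effect size, and
fair-proportion evolutionary distinctiveness.

PD is rooted: the score of a species set is the total branch length on the
union of the tip-to-root paths, so even a single-species cell carries the
full depth of its lineage.  The null model for the standardized effect
size draws equal-richness species sets uniformly without replacement from
the native species pool.  ED divides every branch equally among its
descendant tips and sums each tip's shares along its root path, so ED sums
to the total branch length of the tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gridding import CellMetricMap, GridSpec
from .tree import Tree, TreeError

__all__ = [
    "NullModelConfig",
    "PhyloIndex",
    "prune_tree",
    "faith_pd",
    "pd_map",
    "pd_ses",
    "fair_proportion_ed",
    "ed_category",
    "ed_map",
    "pd_richness_correlation",
]

ED_LOW_CUTOFF = 48.0    # my; boundary values belong to "medium"
ED_HIGH_CUTOFF = 96.0


@dataclass(frozen=True)
class NullModelConfig:
    """Richness-preserving randomization for the PD effect size."""

    n_draws: int = 10_000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def prune_tree(tree: Tree, keep) -> Tree:
    """Restrict the tree to *keep*, preserving patristic distances."""
    return tree.prune(keep)


class PhyloIndex:
    """Caches the tip x branch incidence of a tree for fast repeated PD."""

    def __init__(self, tree: Tree):
        self.tree = tree
        self.tip_order = tree.tip_labels
        self._pos = {name: i for i, name in enumerate(self.tip_order)}
        self.incidence, self.lengths = tree.tip_branch_incidence(self.tip_order)

    def rows(self, species) -> np.ndarray:
        try:
            return np.array([self._pos[s] for s in species], dtype=int)
        except KeyError:
            missing = sorted(set(species) - set(self.tip_order))
            raise TreeError(f"species not in tree: {missing}") from None

    def pd(self, species) -> float:
        rows = self.rows(species)
        if len(rows) == 0:
            raise ValueError("PD is undefined for an empty species set")
        return float(self.lengths @ self.incidence[rows].any(axis=0))

    def pd_many(self, row_sets: np.ndarray) -> np.ndarray:
        """PD of many equal-size sets given as an (n_sets, k) index array."""
        return self.incidence[row_sets].any(axis=1) @ self.lengths


def faith_pd(tree: Tree | PhyloIndex, species) -> float:
    """Sum of branch lengths on the union of tip-to-root paths (rooted PD)."""
    index = tree if isinstance(tree, PhyloIndex) else PhyloIndex(tree)
    return index.pd(set(species))


def pd_map(
    ranges: dict[str, set[tuple[int, int]]],
    tree: Tree,
    grid: GridSpec,
) -> CellMetricMap:
    """Faith's PD of the species present in every occupied cell."""
    missing = sorted(set(ranges) - set(tree.tip_labels))
    if missing:
        raise TreeError(f"species in ranges missing from tree: {missing}")
    index = PhyloIndex(tree)
    by_cell: dict[tuple[int, int], set[str]] = {}
    for sp, cells in ranges.items():
        for cell in cells:
            by_cell.setdefault(cell, set()).add(sp)
    values = {cell: index.pd(spset) for cell, spset in by_cell.items()}
    return CellMetricMap(grid, values, "PD")


def pd_ses(
    tree: Tree | PhyloIndex,
    species,
    pool,
    cfg: NullModelConfig = NullModelConfig(),
) -> tuple[float, float, bool]:
    """Standardized effect size of PD against equal-richness random draws.

    Draws ``cfg.n_draws`` sets of ``len(species)`` species uniformly without
    replacement from *pool*; returns ``(ses, p, significant)`` where
    ``ses = (PDobs - mean(PDnull)) / sd(PDnull)`` and the two-tailed p-value
    uses the (r+1)/(n+1) rank convention.  A set equal to the whole pool is
    degenerate (all draws identical): ses 0, p 1, not significant.
    """
    index = tree if isinstance(tree, PhyloIndex) else PhyloIndex(tree)
    species = set(species)
    pool = sorted(set(pool))
    if not species <= set(pool):
        raise ValueError("species set must be a subset of the pool")
    k = len(species)
    if k == len(pool):
        return 0.0, 1.0, False
    obs = index.pd(species)
    rng = np.random.default_rng(cfg.seed)
    pool_rows = index.rows(pool)
    # uniform k-subsets without replacement, vectorised via random argsort
    perm = np.argsort(rng.random((cfg.n_draws, len(pool_rows))), axis=1)[:, :k]
    null = index.pd_many(pool_rows[perm])
    sd = null.std(ddof=1)
    ses = 0.0 if sd == 0 else float((obs - null.mean()) / sd)
    n = cfg.n_draws
    p_low = (np.sum(null <= obs) + 1) / (n + 1)
    p_high = (np.sum(null >= obs) + 1) / (n + 1)
    p = float(min(1.0, 2 * min(p_low, p_high)))
    return ses, p, p <= cfg.alpha


def ed_category(ed: float) -> str:
    if ed < ED_LOW_CUTOFF:
        return "low"
    if ed <= ED_HIGH_CUTOFF:
        return "medium"
    return "high"


def fair_proportion_ed(tree: Tree) -> pd.DataFrame:
    """Fair-proportion evolutionary distinctiveness per tip.

    Each branch's length is divided by its number of descendant tips; a
    tip's ED is the sum of its shares along the root path.  ED therefore
    sums to the total branch length of the tree.  Categories use the
    48/96-my cutoffs with boundary values in "medium".
    """
    if tree.total_branch_length == 0:
        warnings.warn("zero-length tree: all ED values are 0", stacklevel=2)
    # number of tips below every branch
    n_tips: dict[int, int] = {}
    for node in tree.postorder():
        n_tips[id(node)] = 1 if node.is_tip else sum(
            n_tips[id(c)] for c in node.children
        )
    rows = []
    for tip in tree.tips():
        ed = 0.0
        node = tip
        while node.parent is not None:
            ed += node.length / n_tips[id(node)]
            node = node.parent
        rows.append({"species": tip.name, "ed": ed, "category": ed_category(ed)})
    return pd.DataFrame(rows).sort_values("species").reset_index(drop=True)


def ed_map(
    ranges: dict[str, set[tuple[int, int]]],
    ed_table: pd.DataFrame,
    grid: GridSpec,
) -> CellMetricMap:
    """Per-cell unweighted mean ED of the species present."""
    ed = dict(zip(ed_table["species"], ed_table["ed"]))
    missing = sorted(set(ranges) - set(ed))
    if missing:
        raise TreeError(f"species without an ED value: {missing}")
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for sp, cells in ranges.items():
        for cell in cells:
            sums[cell] = sums.get(cell, 0.0) + ed[sp]
            counts[cell] = counts.get(cell, 0) + 1
    values = {cell: sums[cell] / counts[cell] for cell in sums}
    return CellMetricMap(grid, values, "ED")


def pd_richness_correlation(
    pd_cells: CellMetricMap, richness_cells: CellMetricMap
) -> float:
    """Pearson correlation of PD and richness over their common cells."""
    common = sorted(set(pd_cells.values) & set(richness_cells.values))
    if len(common) < 3:
        raise ValueError("need at least 3 common cells")
    a = np.array([pd_cells.values[c] for c in common])
    b = np.array([richness_cells.values[c] for c in common])
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
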