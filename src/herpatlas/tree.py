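"""Rooted phylogenetic trees with branch lengths.

A small, explicit tree structure is used throughout the diversity
calculations: every node knows its parent, its children and the length of
the branch above it (millions of years for time-calibrated trees).  Newick
parsing and writing are delegated to :mod:`dendropy`; everything else
(pruning, path sums, tip incidence) is implemented directly because those
operations are the substance of the phylogenetic-diversity metrics.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator

import dendropy
import numpy as np

__all__ = ["TreeNode", "Tree", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        kind = "tip" if self.is_tip else f"{len(self.children)} children"
        return f"TreeNode({self.name!r}, length={self.length}, {kind})"


class Tree:
    """Rooted tree with branch lengths.

    The root carries ``length`` 0 by convention.  Tip labels must be unique.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [t.name for t in self.tips()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("every tip must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if any(n.length < 0 for n in self.preorder()):
            raise TreeError("negative branch length")

    # ------------------------------------------------------------- traversal
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tips()]

    @property
    def total_branch_length(self) -> float:
        return sum(n.length for n in self.preorder() if n is not self.root)

    # ------------------------------------------------------------- metrics
    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depth: dict[TreeNode, float] = {self.root: 0.0}
        out: dict[str, float] = {}
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + node.length
            if node.is_tip:
                out[node.name] = depth[node]
        return out

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = list(self.tip_depths().values())
        dmax = max(depths)
        if dmax == 0:
            return True
        return (dmax - min(depths)) <= rel_tol * dmax

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """Pairwise tip-to-tip path lengths (unordered label pairs)."""
        paths: dict[str, dict[TreeNode, float]] = {}
        for tip in self.tips():
            acc, node, d = {}, tip, 0.0
            while node is not None:
                acc[node] = d
                d += node.length
                node = node.parent
            paths[tip.name] = acc
        out: dict[tuple[str, str], float] = {}
        labels = self.tip_labels
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                shared = [n for n in paths[a] if n in paths[b]]
                # the MRCA is the shared ancestor at minimal combined depth
                dist = min(paths[a][n] + paths[b][n] for n in shared)
                out[tuple(sorted((a, b)))] = dist
        return out

    # ------------------------------------------------------------- editing
    def copy(self) -> "Tree":
        def _clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return Tree(_clone(self.root))

    def prune(self, keep: Iterable[str]) -> "Tree":
        """Restrict the tree to the tips in *keep*.

        Unifurcating internal nodes created by the removal are suppressed and
        their branch lengths summed, so root-to-tip depths and patristic
        distances among kept tips are preserved exactly.  The root itself is
        retained even if left with a single child, which keeps the root path
        (and hence rooted phylogenetic diversity) intact.
        """
        keep = set(keep)
        if not keep:
            raise TreeError("cannot prune to an empty tip set")
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise TreeError(f"species not in tree: {sorted(unknown)}")

        def _build(node: TreeNode) -> TreeNode | None:
            if node.is_tip:
                if node.name in keep:
                    return TreeNode(node.name, node.length)
                return None
            kept = [c for c in (_build(ch) for ch in node.children)
                    if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                # suppress the unifurcation; branch lengths sum
                child = kept[0]
                child.length += node.length
                return child
            new = TreeNode(node.name, node.length)
            for c in kept:
                new.add_child(c)
            return new

        # the root itself is never suppressed: rebuild its subtrees and
        # re-attach them, so the root path (and rooted PD) stays intact even
        # when pruning leaves the root unifurcating
        kept = [c for c in (_build(ch) for ch in self.root.children)
                if c is not None]
        new_root = TreeNode(self.root.name, 0.0)
        for c in kept:
            new_root.add_child(c)
        return Tree(new_root)

    # ------------------------------------------------------------- newick
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeError(f"Newick parse error: {exc}") from exc

        def _convert(dnode) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon is not None else None
            if dnode.parent_node is not None and dnode.edge.length is None:
                raise TreeError(
                    f"missing branch length above {name or 'internal node'}"
                )
            node = TreeNode(name, dnode.edge.length or 0.0)
            for dchild in dnode.child_nodes():
                node.add_child(_convert(dchild))
            return node

        return cls(_convert(dtree.seed_node))

    def to_newick(self) -> str:
        def _fmt(node: TreeNode) -> str:
            label = node.name or ""
            if " " in label:
                label = f"'{label}'"
            if node.is_tip:
                return f"{label}:{node.length:.12g}"
            inner = ",".join(_fmt(c) for c in node.children)
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.12g}"

        return _fmt(self.root) + ";"

    # ------------------------------------------------------------- incidence
    def tip_branch_incidence(
        self, tip_order: list[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Boolean tip x branch incidence matrix and branch-length vector.

        Row *i* marks every branch on the path from tip *i* to the root, so
        the phylogenetic diversity of a tip set is
        ``lengths @ incidence[rows].any(axis=0)``.
        """
        branches = [n for n in self.preorder() if n is not self.root]
        index = {id(n): j for j, n in enumerate(branches)}
        lengths = np.array([n.length for n in branches], dtype=float)
        tips = self.tips()
        if tip_order is not None:
            by_name = {t.name: t for t in tips}
            tips = [by_name[name] for name in tip_order]
        B = np.zeros((len(tips), len(branches)), dtype=bool)
        for i, tip in enumerate(tips):
            node = tip
            while node.parent is not None:
                B[i, index[id(node)]] = True
                node = node.parent
        return B, lengths


def check_ultrametric(tree: Tree, rel_tol: float = 1e-6) -> bool:
    """Warn (not fail) when tip depths are unequal beyond tolerance."""
    ok = tree.is_ultrametric(rel_tol)
    if not ok:
        depths = tree.tip_depths()
        warnings.warn(
            "tree is not ultrametric: tip depths range "
            f"{min(depths.values()):.6g}-{max(depths.values()):.6g}",
            stacklevel=2,
        )
    return ok
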