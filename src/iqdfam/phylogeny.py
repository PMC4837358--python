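"""Distance-based neighbour-joining phylogeny with bootstrap support.

Implements Saitou-Nei neighbour joining over p-distances with a
deterministic tie-break (lexicographically smallest pair of cluster
labels), branch lengths from the standard two-point formulas (negative
estimates clamped to 0 and logged), column-bootstrap support values, and
anchor-based subfamily assignment (subfamilies I-IV in this family's
conventional nomenclature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import IqdfamError, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise IqdfamError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise IqdfamError("distance matrix is not symmetric")
        if not np.all(np.isfinite(self.d)) or np.any(np.diag(self.d) != 0):
            raise IqdfamError("distances must be finite with zero diagonal")


@dataclass
class TreeNode:
    name: str | None = None
    branch_length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class PhyloTree:
    """Unrooted tree stored with a (trifurcating) root node."""

    root: TreeNode

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as the smaller/canonical leaf-name side."""
        all_leaves = self.leaf_names()
        out: set[frozenset[str]] = set()
        def walk(node: TreeNode) -> None:
            for c in node.children:
                side = c.leaf_names()
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(_canonical(side, all_leaves))
                walk(c)
        walk(self.root)
        return out

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.branch_length:.6g}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def _canonical(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def p_distance_matrix(aligned: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped columns."""
    if len(aligned) < 3:
        raise IqdfamError("need at least 3 sequences")
    L = len(aligned[0].residues)
    if any(len(r.residues) != L for r in aligned):
        raise IqdfamError("aligned sequences must have equal length")
    labels = [r.id for r in aligned]
    arr = np.array([list(r.residues) for r in aligned])
    gaps = arr == "-"
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            m = int(ok.sum())
            if m == 0:
                raise IqdfamError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            d[i, j] = d[j, i] = float((arr[i, ok] != arr[j, ok]).sum()) / m
    return DistanceMatrix(labels, d)


def _clamp(x: float, edge: str) -> float:
    if x < 0:
        logger.info("negative NJ branch length %.4g at %s clamped to 0", x, edge)
        return 0.0
    return x


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining with Q-criterion agglomeration.

    Ties in Q break to the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf name), making the
    topology deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise IqdfamError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    labels = list(dm.labels)  # cluster label = smallest member leaf name
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - R[i] - R[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        nodes[i].branch_length = _clamp(li, labels[i])
        nodes[j].branch_length = _clamp(lj, labels[j])
        new = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new cluster to the others
        for m in active:
            if m in (i, j):
                continue
            d[i, m] = d[m, i] = (d[i, m] + d[j, m] - d[i, j]) / 2.0
        nodes[i] = new
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = active
    # three-point formulas for the final trifurcation
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    for idx, l in zip((i, j, k), (li, lj, lk)):
        nodes[idx].branch_length = _clamp(l, labels[idx])
    order = sorted((i, j, k), key=lambda x: labels[x])
    root = TreeNode(children=[nodes[x] for x in order])
    return PhyloTree(root=root)


def bootstrap_support(
    aligned: Sequence[SequenceRecord], n_replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree with column-bootstrap support on internal bipartitions.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each internal bipartition of
    the tree built from the full alignment.  Fully seeded.
    """
    tree = nj_tree(p_distance_matrix(aligned))
    if n_replicates <= 0:
        return tree
    rng = np.random.default_rng(seed)
    L = len(aligned[0].residues)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        resampled = [
            SequenceRecord(r.id, r.description, "".join(r.residues[c] for c in cols))
            for r in aligned
        ]
        rep = nj_tree(p_distance_matrix(resampled))
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    universe = tree.leaf_names()
    def annotate(node: TreeNode) -> None:
        for c in node.children:
            if not c.is_leaf:
                side = c.leaf_names()
                if 1 < len(side) < len(universe) - 1:
                    c.support = 100.0 * counts.get(_canonical(side, universe), 0) / n_replicates
            annotate(c)
    annotate(tree.root)
    return tree


@dataclass
class SubfamilyAssignment:
    assignments: dict[str, str | None]
    anchors: dict[str, str]


def assign_subfamilies(
    tree: PhyloTree, anchors: Mapping[str, str]
) -> SubfamilyAssignment:
    """Label each query leaf by the subfamily of the smallest anchored
    clade containing it.

    Because the tree is unrooted, a "clade" is either side of any edge.
    For each query leaf the smallest side containing the leaf and at least
    one anchor decides its label, provided that side carries anchors of
    only one subfamily and no equally small side disagrees; otherwise the
    leaf is unresolved (None).  Subfamilies without any anchor in the tree
    trigger a warning and stay unassignable.
    """
    universe = tree.leaf_names()
    present = {a: s for a, s in anchors.items() if a in universe}
    missing_subfams = set(anchors.values()) - set(present.values())
    for s in sorted(missing_subfams):
        logger.warning("no anchor present in tree for subfamily %s", s)

    sides: set[frozenset[str]] = set()
    def collect(node: TreeNode) -> None:
        for c in node.children:
            side = c.leaf_names()
            if side != universe:
                sides.add(side)
                sides.add(universe - side)
            collect(c)
    collect(tree.root)

    assignments: dict[str, str | None] = {}
    for leaf in tree.root.leaves():
        if leaf.name in present:
            continue
        candidates = [
            s for s in sides if leaf.name in s and any(a in s for a in present)
        ]
        if not candidates:
            assignments[leaf.name] = None
            continue
        smallest = min(len(s) for s in candidates)
        labels = set()
        for s in (c for c in candidates if len(c) == smallest):
            subfams = {present[a] for a in s if a in present}
            labels |= subfams if len(subfams) == 1 else {None}
        assignments[leaf.name] = labels.pop() if len(labels) == 1 else None
    return SubfamilyAssignment(assignments=assignments, anchors=dict(present))
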