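"""Distance-based clustering of transcription-factor proteins.

Implements p-distances on a pre-computed multiple alignment, Saitou-Nei
neighbor joining, bootstrap support over alignment columns, and anchor-based
extraction of family groups (e.g. the ARF clade) from the resulting tree.

The alignment itself is an input: the pipeline assumes it was produced by an
external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .go_mining import GeneSet
from .io_formats import SequenceRecord

__all__ = [
    "AlignedSequenceSet",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "extract_family_groups",
]

GAP_CHARS = {"-", "."}


@dataclass
class AlignedSequenceSet:
    """Equal-length gapped sequences (columns of a multiple alignment)."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def labels(self) -> list[str]:
        return [r.id for r in self.records]

    def column_subset(self, columns: Sequence[int]) -> "AlignedSequenceSet":
        recs = [
            SequenceRecord(r.id, r.description, "".join(r.residues[c] for c in columns))
            for r in self.records
        ]
        return AlignedSequenceSet(recs)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.d = d


def p_distance(aln: AlignedSequenceSet) -> DistanceMatrix:
    """Pairwise mismatch proportion with pairwise deletion of gap columns."""
    labels = aln.labels()
    seqs = [np.frombuffer(r.residues.encode(), dtype="S1") for r in aln.records]
    gap = [np.isin(s, [c.encode() for c in GAP_CHARS]) for s in seqs]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = float((seqs[i][ok] != seqs[j][ok]).sum()) / m
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent; meaningless for the root
    support: float | None = None  # bootstrap % for the edge above this node
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


class PhyloTree:
    """An unrooted tree stored rooted at the final agglomeration point."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def n_edges(self) -> int:
        def count(node: TreeNode) -> int:
            return len(node.children) + sum(count(c) for c in node.children)

        return count(self.root)

    def _edge_sides(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """(child node, leaf set under it) for every edge."""
        out: list[tuple[TreeNode, frozenset[str]]] = []

        def walk(node: TreeNode) -> None:
            for c in node.children:
                out.append((c, c.leaf_names()))
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Canonical non-trivial splits (both sides with >= 2 leaves)."""
        all_leaves = self.leaf_names()
        splits: set[frozenset[frozenset[str]]] = set()
        for _, side in self._edge_sides():
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(frozenset({side, other}))
        return splits

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf distances along tree edges."""
        import networkx as nx

        g = nx.Graph()
        counter = [0]

        def ident(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            if not hasattr(node, "_pid"):
                node._pid = f"__internal_{counter[0]}"
                counter[0] += 1
            return node._pid

        def walk(node: TreeNode) -> None:
            for c in node.children:
                g.add_edge(ident(node), ident(c), weight=c.length)
                walk(c)

        walk(self.root)
        labels = sorted(self.leaf_names())
        n = len(labels)
        d = np.zeros((n, n))
        lengths = dict(nx.all_pairs_dijkstra_path_length(g))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = lengths[a][labels[j]]
        return DistanceMatrix(labels, d)

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            if top:
                return f"({inner}){label};"
            return f"({inner}){label}:{node.length:.10g}"

        return fmt(self.root, top=True)


# ---------------------------------------------------------------------------
# Neighbor joining


def _node_key(node: TreeNode) -> str:
    """Deterministic label for tie-breaking: smallest leaf name underneath."""
    return min(l.name for l in node.leaves())


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration.

    Exact on additive matrices (reproduces all pairwise path lengths).
    Q-matrix ties are broken by the lexicographically smallest label pair;
    negative branch lengths are clamped to zero with the deficit transferred
    to the sister edge so the joined pair's distance is preserved.
    """
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    D = dm.d.copy()

    if len(nodes) == 2:
        half = D[0, 1] / 2.0
        nodes[0].length = nodes[1].length = half
        return PhyloTree(TreeNode(children=nodes))

    def pick_pair(Q: np.ndarray) -> tuple[int, int]:
        qmin = Q.min()
        ii, jj = np.nonzero(Q == qmin)
        best = None
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            a, b = sorted((_node_key(nodes[i]), _node_key(nodes[j])))
            cand = (a, b, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        return best[2], best[3]

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj = max(lj + li, 0.0)
            li = 0.0
        elif lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # add the rank sums first: r_i + r_j is exactly symmetric, whereas
        # ((m-2)d - r_i) - r_j is not, and pick_pair relies on exact ties
        Q = (m - 2) * D - (r[:, None] + r[None, :])
        np.fill_diagonal(Q, np.inf)
        i, j = pick_pair(Q)
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[m - 2, : m - 2] = D2[: m - 2, m - 2] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final 3-way (or, for n == 3 input, the only) junction
    (a, b, c) = nodes
    la = max((D[0, 1] + D[0, 2] - D[1, 2]) / 2.0, 0.0)
    lb = max((D[0, 1] + D[1, 2] - D[0, 2]) / 2.0, 0.0)
    lc = max((D[0, 2] + D[1, 2] - D[0, 1]) / 2.0, 0.0)
    a.length, b.length, c.length = la, lb, lc
    return PhyloTree(TreeNode(children=[a, b, c]))


def bootstrap_support(
    aln: AlignedSequenceSet, replicates: int, seed: int
) -> PhyloTree:
    """NJ tree from the full alignment, with bootstrap split support.

    Columns are resampled with replacement; each internal edge's support is
    the percentage of replicate trees containing the same bipartition.
    Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(p_distance(aln))
    target = {
        frozenset({side, tree.leaf_names() - side}): node
        for node, side in tree._edge_sides()
        if len(side) >= 2 and len(tree.leaf_names() - side) >= 2
    }
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = neighbor_joining(p_distance(aln.column_subset(cols)))
        rep_splits = rep.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in target.items():
        node.support = 100.0 * counts[split] / replicates
    return tree


def extract_family_groups(
    tree: PhyloTree, anchors: Mapping[str, str]
) -> dict[str, GeneSet]:
    """Assign unlabeled leaves to anchored families.

    Each unlabeled leaf takes the label of the smallest clade (side of any
    tree edge) containing it together with at least one anchor, provided
    that clade's anchors belong to a single family; leaves whose smallest
    anchored clade mixes families are reported under ``"unassigned"``.
    """
    leaf_names = set(tree.leaf_names())
    missing = [a for a in anchors if a not in leaf_names]
    if missing:
        raise ValueError(f"anchors absent from tree: {sorted(missing)}")

    all_leaves = frozenset(leaf_names)
    sides: list[frozenset[str]] = []
    for _, side in tree._edge_sides():
        sides.append(side)
        sides.append(all_leaves - side)

    groups: dict[str, set[str]] = {}
    unassigned: set[str] = set()
    for leaf in sorted(leaf_names):
        if leaf in anchors:
            groups.setdefault(anchors[leaf], set()).add(leaf)
            continue
        candidates = [
            s for s in sides if leaf in s and any(x in anchors for x in s)
        ]
        if not candidates:
            unassigned.add(leaf)
            continue
        min_size = min(len(s) for s in candidates)
        families = {
            anchors[x]
            for s in candidates
            if len(s) == min_size
            for x in s
            if x in anchors
        }
        if len(families) == 1:
            groups.setdefault(families.pop(), set()).add(leaf)
        else:
            unassigned.add(leaf)

    out = {fam: GeneSet(label=fam, genes=g) for fam, g in sorted(groups.items())}
    if unassigned:
        out["unassigned"] = GeneSet(label="unassigned", genes=unassigned)
    return out
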