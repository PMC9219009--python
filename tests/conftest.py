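"""Shared fixtures and independent oracle helpers for the test suite.

The oracles here deliberately avoid the package's own code paths: additive
distance matrices are built on raw networkx graphs, motif p-values come
from explicit 4^w enumeration, hypergeometric tails from exact rational
arithmetic, and Mann-Whitney p-values from enumeration of labelings.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------------------
# Additive-tree oracle (independent of the package's tree classes)


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random unrooted binary tree with positive branch lengths.

    Returns (labels, distance_matrix, set_of_canonical_splits). Built by
    repeatedly subdividing a uniformly chosen edge and hanging a new leaf.
    """
    assert n_leaves >= 3
    g = nx.Graph()
    center = "I0"
    leaves = [f"L{i}" for i in range(n_leaves)]
    for leaf in leaves[:3]:
        g.add_edge(center, leaf, weight=float(rng.uniform(0.05, 1.0)))
    internal_count = 1
    for leaf in leaves[3:]:
        edges = list(g.edges(data=True))
        u, v, data = edges[rng.integers(0, len(edges))]
        g.remove_edge(u, v)
        mid = f"I{internal_count}"
        internal_count += 1
        w = data["weight"]
        split = float(rng.uniform(0.25, 0.75))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, leaf, weight=float(rng.uniform(0.05, 1.0)))

    labels = sorted(leaves)
    dists = dict(nx.all_pairs_dijkstra_path_length(g))
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dists[a][labels[j]]
    return labels, D, tree_splits(g, set(leaves))


def tree_splits(g: nx.Graph, leaves: set[str]) -> set[frozenset[frozenset[str]]]:
    """Canonical non-trivial bipartitions of an undirected tree."""
    splits = set()
    for u, v in list(g.edges()):
        g2 = g.copy()
        g2.remove_edge(u, v)
        side = set(nx.node_connected_component(g2, u)) & leaves
        other = leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({frozenset(side), frozenset(other)}))
    return splits


def five_taxon_topologies(labels):
    """All 15 unrooted binary topologies on 5 leaves.

    Each is returned as (graph with unit edges, canonical splits).
    """
    assert len(labels) == 5
    base = nx.Graph()
    base.add_edges_from(("C0", l) for l in labels[:3])
    trees = [base]
    for idx, leaf in enumerate(labels[3:], start=1):
        grown = []
        for t in trees:
            for u, v in list(t.edges()):
                t2 = t.copy()
                t2.remove_edge(u, v)
                mid = f"M{idx}_{u}_{v}"
                t2.add_edge(u, mid)
                t2.add_edge(mid, v)
                t2.add_edge(mid, leaf)
                grown.append(t2)
        trees = grown
    out = []
    leafset = set(labels)
    for t in trees:
        out.append((t, tree_splits(t, leafset)))
    assert len(out) == 15
    return out


def best_fit_topology_splits(labels, D):
    """Least-squares best additive fit over all 15 five-taxon topologies."""
    pairs = list(itertools.combinations(range(5), 2))
    best = None
    for g, splits in five_taxon_topologies(labels):
        edges = list(g.edges())
        A = np.zeros((len(pairs), len(edges)))
        y = np.array([D[i, j] for i, j in pairs])
        for row, (i, j) in enumerate(pairs):
            path = nx.shortest_path(g, labels[i], labels[j])
            on_path = {frozenset(e) for e in zip(path, path[1:])}
            for col, e in enumerate(edges):
                if frozenset(e) in on_path:
                    A[row, col] = 1.0
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ x - y) ** 2).sum())
        if best is None or resid < best[0]:
            best = (resid, splits)
    return best[1]


# ---------------------------------------------------------------------------
# Motif-scan enumeration oracle


def enumerate_word_scores(lom: np.ndarray, background: np.ndarray):
    """Scores and probabilities of all 4^w words, summed left to right."""
    scores = np.zeros(1)
    probs = np.ones(1)
    for row in lom:
        scores = (scores[:, None] + row[None, :]).ravel()
        probs = (probs[:, None] * background[None, :]).ravel()
    return scores, probs


def enumeration_pvalue(lom: np.ndarray, background: np.ndarray, s: float) -> float:
    scores, probs = enumerate_word_scores(lom, background)
    return float(probs[scores >= s].sum())


# ---------------------------------------------------------------------------
# Exact hypergeometric and Mann-Whitney oracles


def hypergeom_tail_exact(x: int, n: int, k: int, N: int) -> float:
    """Upper tail by exact rational combinatorial sum."""
    total = Fraction(0)
    denom = math.comb(N, k)
    for i in range(x, min(n, k) + 1):
        if k - i <= N - n:
            total += Fraction(math.comb(n, i) * math.comb(N - n, k - i), denom)
    return float(total)


def mannwhitney_exact_enumeration(a, b) -> float:
    """Two-sided p by enumerating all assignments of the pooled values."""
    a = list(a)
    b = list(b)
    pooled = a + b
    na = len(a)

    def u_stat(group_a):
        u = 0
        rest = list(pooled)
        for x in group_a:
            rest.remove(x)
        for x in group_a:
            for y in rest:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_stat(a)
    n_ab = na * len(b)
    dev_obs = abs(u_obs - n_ab / 2)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        group = [pooled[i] for i in combo]
        total += 1
        if abs(u_stat(group) - n_ab / 2) >= dev_obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """A fully simulated input directory, shared across tests."""
    from arfnet.synthetic_data import SimulationSpec, simulate

    out = tmp_path_factory.mktemp("simdata")
    spec = SimulationSpec(seed=11)
    paths = simulate(spec, out)
    return spec, paths
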