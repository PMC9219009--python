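"""Gene-ontology enrichment network maps.

From a target-gene set, annotations and an ontology DAG this module applies
the true-path rule (annotation propagation to ancestors), tests every
biological-process term by the hypergeometric upper tail, corrects for
multiple testing, and assembles the significant-term subgraph together with
its ancestor scaffold — the "network map". Maps built for different query
TF sets are compared by their counts of keyword-matching ("root"-related)
significant nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.special import gammaln

from .go_mining import AnnotationTable, GeneSet
from .io_formats import log

__all__ = [
    "OntologyGraph",
    "EnrichmentResult",
    "EnrichmentNetwork",
    "read_obo",
    "propagate_annotations",
    "hypergeometric_test",
    "correct_pvalues",
    "build_map",
    "count_keyword_nodes",
    "compare_maps",
    "enrichment_table",
]

_PROPAGATING_RELATIONS = {"is_a", "part_of"}


class OntologyGraph:
    """Directed acyclic term graph with child-to-parent edges.

    Wraps a :class:`networkx.DiGraph` whose nodes carry ``name`` and
    ``namespace`` attributes; only ``is_a`` and ``part_of`` edges propagate
    annotations.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")
        self.graph = graph
        self._ancestors: dict[str, frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", term_id)

    def namespace(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("namespace", "")

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` through propagating edges."""
        if term_id not in self._ancestors:
            self._ancestors[term_id] = frozenset(nx.descendants(self.graph, term_id))
        return self._ancestors[term_id]

    def roots(self, namespace: str | None = None) -> list[str]:
        out = [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]
        if namespace is not None:
            out = [t for t in out if self.namespace(t) == namespace]
        return out


def read_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO file (id, name, namespace, is_a, relationship part_of).

    obonet returns edges child-to-parent already; edges other than is_a and
    part_of are dropped.
    """
    raw = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for node, data in raw.nodes(data=True):
        g.add_node(node, name=data.get("name", node), namespace=data.get("namespace", ""))
    for child, parent, key in raw.edges(keys=True):
        if key in _PROPAGATING_RELATIONS:
            g.add_edge(child, parent, relation=key)
    return OntologyGraph(g)


@dataclass
class EnrichmentResult:
    """Hypergeometric statistics for a single term.

    x study genes out of k hit a term annotated to n of N population genes.
    """

    term_id: str
    term_name: str
    x: int
    n: int
    k: int
    N: int
    p: float
    q: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.n, self.k) and self.k <= self.N and self.n <= self.N):
            raise ValueError(
                f"inconsistent counts for {self.term_id}: x={self.x} n={self.n} "
                f"k={self.k} N={self.N}"
            )


class EnrichmentNetwork:
    """Significant terms plus their ancestor scaffold, as a DiGraph.

    Node attributes: ``term_name``, ``gene_count`` (x), ``p``, ``q``,
    ``significant``. Graph attributes carry the funnel counts used in map
    comparison (``label``, ``n_coexpressed``, ``n_targets``).
    """

    def __init__(self, graph: nx.DiGraph, label: str = ""):
        self.graph = graph
        self.graph.graph.setdefault("label", label)

    @property
    def label(self) -> str:
        return self.graph.graph.get("label", "")

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def significant_nodes(self) -> list[str]:
        return [t for t, d in self.graph.nodes(data=True) if d.get("significant")]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def propagate_annotations(
    annotations: AnnotationTable, dag: OntologyGraph
) -> dict[str, set[str]]:
    """True-path rule: term -> genes annotated to it or any descendant.

    Annotation lines whose term is absent from the DAG are logged and
    skipped. Idempotent: propagating an already-propagated map changes
    nothing.
    """
    term_genes: dict[str, set[str]] = {}
    missing: set[str] = set()
    for rec in annotations:
        if rec.term_id not in dag:
            missing.add(rec.term_id)
            continue
        term_genes.setdefault(rec.term_id, set()).add(rec.gene_id)
        for anc in dag.ancestors(rec.term_id):
            term_genes.setdefault(anc, set()).add(rec.gene_id)
    if missing:
        log("warning", f"{len(missing)} annotation term(s) absent from ontology; skipped")
    return term_genes


def hypergeometric_test(x: int, n: int, k: int, N: int) -> float:
    """Upper-tail hypergeometric p-value, summed in log space.

    p = sum_{i=x}^{min(n,k)} C(n,i) C(N-n,k-i) / C(N,k).
    """
    if x > min(n, k):
        raise ValueError(f"x={x} exceeds min(n={n}, k={k})")
    if x < 0 or n > N or k > N:
        raise ValueError(f"inconsistent parameters x={x} n={n} k={k} N={N}")
    if x == 0:
        return 1.0

    def log_comb(a: int, b: int) -> float:
        return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))

    denom = log_comb(N, k)
    terms = []
    for i in range(x, min(n, k) + 1):
        if k - i > N - n:
            continue
        terms.append(log_comb(n, i) + log_comb(N - n, k - i) - denom)
    if not terms:
        return 0.0
    mx = max(terms)
    total = mx + math.log(sum(math.exp(t - mx) for t in terms))
    return float(min(math.exp(total), 1.0))


def correct_pvalues(ps: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing correction, order restored to the input order.

    ``BH`` (Benjamini-Hochberg step-up, the default), ``bonferroni`` or
    ``none``.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps
    if ((ps <= 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    method = method.lower()
    if method == "none":
        return ps.copy()
    from statsmodels.stats.multitest import multipletests

    name = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if name is None:
        raise ValueError(f"unknown correction {method!r}; use BH, bonferroni or none")
    return multipletests(ps, method=name)[1]


def build_map(
    targets,
    annotations: AnnotationTable,
    dag: OntologyGraph,
    population: GeneSet | None = None,
    q_max: float = 0.05,
    namespace: str = "biological_process",
    correction: str = "BH",
    label: str | None = None,
) -> EnrichmentNetwork:
    """Enrichment network map for a target-gene set.

    Tests every term of the chosen namespace with at least one study and one
    population gene after true-path propagation; terms with corrected
    q <= q_max become significant nodes and their ancestors are added as
    non-significant context so the map stays connected to the namespace
    root. The population defaults to all genes with at least one propagated
    annotation in the namespace.
    """
    term_genes = propagate_annotations(annotations, dag)
    ns_terms = [t for t in term_genes if dag.namespace(t) == namespace or not namespace]

    if population is None:
        pop_genes: set[str] = set()
        for t in ns_terms:
            pop_genes |= term_genes[t]
        population = GeneSet(label="annotated", genes=pop_genes)

    target_genes = set(getattr(targets, "genes", targets))
    study = target_genes & population.genes
    k, N = len(study), len(population.genes)

    results: list[EnrichmentResult] = []
    for t in sorted(ns_terms):
        genes_t = term_genes[t] & population.genes
        n = len(genes_t)
        x = len(genes_t & study)
        if n < 1 or x < 1:
            continue
        p = hypergeometric_test(x, n, k, N)
        results.append(EnrichmentResult(t, dag.name(t), x, n, k, N, p))

    if results:
        qs = correct_pvalues([r.p for r in results], method=correction)
        for r, q in zip(results, qs):
            r.q = float(q)

    g = nx.DiGraph()
    significant = [r for r in results if r.q <= q_max]
    by_term = {r.term_id: r for r in results}
    keep: set[str] = set()
    for r in significant:
        keep.add(r.term_id)
        keep |= set(dag.ancestors(r.term_id))
    for t in sorted(keep):
        r = by_term.get(t)
        g.add_node(
            t,
            term_name=dag.name(t),
            gene_count=int(r.x) if r else 0,
            p=float(r.p) if r else 1.0,
            q=float(r.q) if r else 1.0,
            significant=bool(r and r.q <= q_max),
        )
    for child, parent in dag.graph.edges():
        if child in keep and parent in keep:
            g.add_edge(child, parent)

    net = EnrichmentNetwork(g, label=label or getattr(targets, "query_label", ""))
    net.graph.graph["n_targets"] = len(target_genes)
    net.graph.graph["n_coexpressed"] = getattr(targets, "n_coexpressed", 0)
    net.results = results
    return net


def count_keyword_nodes(
    net: EnrichmentNetwork, keywords: Sequence[str] = ("root",)
) -> int:
    """Significant nodes whose term name contains any keyword (case-insensitive)."""
    lowered = [k.lower() for k in keywords]
    count = 0
    for t in net.significant_nodes():
        name = net.graph.nodes[t].get("term_name", "").lower()
        if any(k in name for k in lowered):
            count += 1
    return count


def compare_maps(
    maps: Sequence[EnrichmentNetwork],
    labels: Sequence[str] | None = None,
    keywords: Sequence[str] = ("root",),
) -> pd.DataFrame:
    """Side-by-side summary of several maps.

    Rows: co-expressed gene count, motif-passing gene count, node count and
    keyword-matching node count; one column per map.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps to compare")
    labels = list(labels) if labels is not None else [m.label or f"map{i}" for i, m in enumerate(maps)]
    rows = {
        "coexpressed_genes": [m.graph.graph.get("n_coexpressed", 0) for m in maps],
        "motif_passing_genes": [m.graph.graph.get("n_targets", 0) for m in maps],
        "nodes": [len(m.significant_nodes()) for m in maps],
        "keyword_nodes": [count_keyword_nodes(m, keywords) for m in maps],
    }
    return pd.DataFrame(rows, index=labels).T


def enrichment_table(net: EnrichmentNetwork) -> pd.DataFrame:
    """All tested terms as a DataFrame (term_id, name, x, n, k, N, p, q)."""
    results = getattr(net, "results", [])
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "x": r.x,
                "n": r.n,
                "k": r.k,
                "N": r.N,
                "p": r.p,
                "q": r.q,
            }
            for r in sorted(results, key=lambda r: (r.p, r.term_id))
        ]
    )
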