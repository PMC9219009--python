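"""True-path propagation, hypergeometric enrichment, BH, map building."""

import networkx as nx
import numpy as np
import pytest
from conftest import hypergeom_tail_exact
from scipy import stats

from arfnet.enrichment_network import (
    EnrichmentNetwork,
    OntologyGraph,
    build_map,
    compare_maps,
    correct_pvalues,
    count_keyword_nodes,
    enrichment_table,
    hypergeometric_test,
    propagate_annotations,
    read_obo,
)
from arfnet.go_mining import AnnotationRecord, AnnotationTable, GeneSet


def dag_from_edges(edges, names=None):
    g = nx.DiGraph()
    nodes = {n for e in edges for n in e}
    for n in nodes:
        g.add_node(n, name=(names or {}).get(n, n), namespace="biological_process")
    g.add_edges_from(edges)
    return OntologyGraph(g)


def ann(gene, term, name="x"):
    return AnnotationRecord(gene, term, name, "P", "IEA")


class TestPropagation:
    def test_root_only_annotation_stays_at_root(self):
        dag = dag_from_edges([("b", "root")])
        got = propagate_annotations(AnnotationTable([ann("g", "root")]), dag)
        assert got == {"root": {"g"}}

    def test_chain_transitive_closure(self):
        dag = dag_from_edges([("a", "b"), ("b", "c")])
        got = propagate_annotations(AnnotationTable([ann("g", "a")]), dag)
        assert got == {"a": {"g"}, "b": {"g"}, "c": {"g"}}

    def test_idempotence(self):
        dag = dag_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        table = AnnotationTable([ann("g1", "a"), ann("g2", "b")])
        once = propagate_annotations(table, dag)
        again_records = [
            ann(g, t) for t, genes in once.items() for g in genes
        ]
        twice = propagate_annotations(AnnotationTable(again_records), dag)
        assert once == twice

    def test_random_dag_matches_boolean_closure_oracle(self):
        rng = np.random.default_rng(17)
        n_terms = 50
        terms = [f"T{i}" for i in range(n_terms)]
        edges = []
        for i in range(1, n_terms):
            for parent in rng.choice(i, size=min(i, 2), replace=False):
                edges.append((terms[i], terms[parent]))
        dag = dag_from_edges(edges)
        # random annotations
        genes = [f"g{i}" for i in range(30)]
        records = []
        direct = np.zeros((len(genes), n_terms), dtype=bool)
        for gi, g in enumerate(genes):
            for ti in rng.choice(n_terms, size=3, replace=False):
                records.append(ann(g, terms[ti]))
                direct[gi, ti] = True
        # oracle: boolean reachability matrix product
        A = np.eye(n_terms, dtype=bool)
        E = np.zeros((n_terms, n_terms), dtype=bool)
        for c, p in edges:
            E[terms.index(c), terms.index(p)] = True
        reach = A.copy()
        for _ in range(n_terms):
            new = reach | (reach @ E)
            if (new == reach).all():
                break
            reach = new
        expected = direct @ reach  # gene x term propagated
        got = propagate_annotations(AnnotationTable(records), dag)
        for ti, t in enumerate(terms):
            assert got.get(t, set()) == {genes[gi] for gi in np.nonzero(expected[:, ti])[0]}

    def test_missing_term_skipped(self):
        dag = dag_from_edges([("a", "b")])
        got = propagate_annotations(AnnotationTable([ann("g", "zzz")]), dag)
        assert got == {}

    def test_cycle_rejected(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="cycle"):
            OntologyGraph(g)


class TestHypergeometric:
    def test_term_covering_population_gives_one(self):
        for x in range(6):
            assert hypergeometric_test(x, 20, 5, 20) == pytest.approx(1.0)

    def test_zero_overlap_gives_one(self):
        assert hypergeometric_test(0, 4, 5, 20) == 1.0

    def test_worked_combinatorial_example(self):
        from math import comb

        expected = (comb(4, 3) * comb(16, 2) + comb(4, 4) * comb(16, 1)) / comb(20, 5)
        assert hypergeometric_test(3, 4, 5, 20) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            N = int(rng.integers(5, 26))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(1, N + 1))
            x = int(rng.integers(0, min(n, k) + 1))
            assert hypergeometric_test(x, n, k, N) == pytest.approx(
                hypergeom_tail_exact(x, n, k, N), abs=1e-12
            )

    def test_matches_scipy_survival_function(self):
        assert hypergeometric_test(7, 30, 20, 100) == pytest.approx(
            float(stats.hypergeom.sf(6, 100, 30, 20)), rel=1e-9
        )

    def test_pmf_sums_to_one(self):
        N, n, k = 25, 11, 9
        total = sum(
            hypergeometric_test(x, n, k, N) - hypergeometric_test(x + 1, n, k, N)
            if x + 1 <= min(n, k)
            else hypergeometric_test(x, n, k, N)
            for x in range(0, min(n, k) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_x_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_test(6, 4, 5, 20)


class TestCorrection:
    def test_single_p_unchanged(self):
        assert correct_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        qs = correct_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(qs, 0.04)

    def test_qs_dominate_ps_and_input_order_restored(self):
        rng = np.random.default_rng(2)
        ps = rng.uniform(0.001, 1.0, size=40)
        qs = correct_pvalues(ps)
        assert (qs >= ps - 1e-15).all()
        # monotone with respect to p-order
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-15).all()

    def test_bonferroni_and_none(self):
        ps = [0.01, 0.2]
        assert np.allclose(correct_pvalues(ps, "bonferroni"), [0.02, 0.4])
        assert np.allclose(correct_pvalues(ps, "none"), ps)


class TestBuildMap:
    @pytest.fixture
    def planted(self):
        from arfnet.synthetic_data import (
            SimulationSpec,
            generate_annotations,
            generate_ontology,
            planted_term,
        )

        spec = SimulationSpec(seed=13)
        dag = generate_ontology(spec)
        table = generate_annotations(spec, dag)
        return spec, dag, table, planted_term(spec)

    def test_planted_term_flagged_with_ancestor_context(self, planted):
        spec, dag, table, pt = planted
        net = build_map(GeneSet("study", set(spec.block_gene_ids())), table, dag)
        assert pt in net.significant_nodes()
        for anc in dag.ancestors(pt):
            assert anc in net.graph
        non_sig = [t for t in net.graph if not net.graph.nodes[t]["significant"]]
        assert set(dag.ancestors(pt)) - set(net.significant_nodes()) <= set(non_sig)

    def test_empty_target_set_gives_empty_network(self, planted):
        spec, dag, table, _ = planted
        net = build_map(GeneSet("none", set()), table, dag)
        assert len(net) == 0
        assert net.significant_nodes() == []

    def test_no_significant_terms_possible_with_tiny_study(self):
        dag = dag_from_edges([("a", "root"), ("b", "root")])
        table = AnnotationTable([ann(f"g{i}", "a") for i in range(5)] +
                                [ann(f"h{i}", "b") for i in range(5)])
        net = build_map(GeneSet("s", {"g0"}), table, dag)
        assert net.significant_nodes() == []

    def test_planted_recovery_rate(self, planted):
        """Planting is detected at q<=0.05 in nearly all seeded replicates."""
        from arfnet.synthetic_data import (
            SimulationSpec,
            generate_annotations,
            generate_ontology,
            planted_term,
        )

        hits = 0
        n_rep = 200
        for s in range(n_rep):
            spec = SimulationSpec(seed=40_000 + s, n_genes=120, n_terms=40)
            dag = generate_ontology(spec)
            table = generate_annotations(spec, dag)
            net = build_map(GeneSet("study", set(spec.block_gene_ids())), table, dag)
            if planted_term(spec) in net.significant_nodes():
                hits += 1
        assert hits / n_rep >= 0.95


class TestKeywordCountingAndComparison:
    def _net(self, names_sig, names_ctx=()):
        g = nx.DiGraph()
        for i, name in enumerate(names_sig):
            g.add_node(f"S{i}", term_name=name, significant=True, gene_count=1, p=0.01, q=0.01)
        for i, name in enumerate(names_ctx):
            g.add_node(f"C{i}", term_name=name, significant=False, gene_count=0, p=1.0, q=1.0)
        return EnrichmentNetwork(g, label="fixture")

    def test_empty_network_counts_zero(self):
        assert count_keyword_nodes(EnrichmentNetwork(nx.DiGraph())) == 0

    def test_substring_count_over_significant_nodes(self):
        net = self._net(
            ["root morphogenesis", "leaf development", "root hair cell differentiation"]
        )
        assert count_keyword_nodes(net) == 2

    def test_context_ancestors_not_counted(self):
        net = self._net(["leaf development"], names_ctx=["root system development"])
        assert count_keyword_nodes(net) == 0

    def test_identical_maps_identical_columns(self):
        a = self._net(["root growth", "other"])
        b = self._net(["root growth", "other"])
        table = compare_maps([a, b], labels=["A", "B"])
        assert (table["A"] == table["B"]).all()

    def test_comparison_round_trips_tsv(self, tmp_path):
        a = self._net(["root growth"])
        b = self._net(["leaf growth"])
        table = compare_maps([a, b], labels=["A", "B"])
        p = tmp_path / "cmp.tsv"
        table.to_csv(p, sep="\t")
        import pandas as pd

        back = pd.read_csv(p, sep="\t", index_col=0)
        assert (back == table).all().all()
        assert table.loc["keyword_nodes", "A"] == 1
        assert table.loc["keyword_nodes", "B"] == 0


class TestOboRoundTrip:
    def test_generated_obo_parses_with_names_and_edges(self, tmp_path):
        from arfnet.synthetic_data import SimulationSpec, generate_ontology

        spec = SimulationSpec(seed=3, n_terms=25)
        p = tmp_path / "onto.obo"
        direct = generate_ontology(spec, p)
        parsed = read_obo(p)
        assert set(parsed.terms()) == set(direct.terms())
        assert set(parsed.graph.edges()) == set(direct.graph.edges())
        for t in parsed.terms():
            assert parsed.name(t) == direct.name(t)
            assert parsed.namespace(t) == "biological_process"
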