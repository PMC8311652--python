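"""Ontology parsing, true-path propagation, the Fisher ORA, and DAG roles."""

import io
import math
import random
import textwrap
from itertools import combinations

import networkx as nx
import pytest

from epipharm.ora import (
    AnnotationIndex,
    ORAConfig,
    OntologyError,
    annotate_dag_roles,
    export_dag,
    parse_ontology,
    propagate_annotations,
    run_ora,
)


def make_dag(edges, namespace="molecular_function"):
    """Build an OntologyDag from (child, parent, relation) triples."""
    stanzas = ["format-version: 1.2", "ontology: test", ""]
    nodes = sorted({n for e in edges for n in e[:2]})
    for node in nodes:
        stanzas += ["[Term]", f"id: {node}", f"name: {node}", f"namespace: {namespace}"]
        for child, parent, rel in edges:
            if child == node:
                stanzas.append(
                    f"is_a: {parent}" if rel == "is_a" else f"relationship: {rel} {parent}"
                )
        stanzas.append("")
    return parse_ontology(io.StringIO("\n".join(stanzas)))


class TestParseOntology:
    def test_three_term_chain(self, chain_dag):
        prop = chain_dag.propagation_graph()
        assert prop.number_of_edges() == 2
        assert chain_dag.roots() == ["T:0000001"]

    def test_obsolete_term_excluded(self):
        obo = textwrap.dedent(
            """\
            format-version: 1.2
            ontology: test

            [Term]
            id: T:1
            name: keep

            [Term]
            id: T:2
            name: gone
            is_obsolete: true
            """
        )
        dag = parse_ontology(io.StringIO(obo))
        assert dag.terms == ["T:1"]

    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            make_dag([("A", "B", "is_a"), ("B", "A", "is_a")])

    def test_regulates_not_in_propagation_graph(self):
        dag = make_dag([("A", "R", "is_a"), ("A", "B", "regulates"), ("B", "R", "is_a")])
        prop = dag.propagation_graph()
        assert not prop.has_edge("A", "B")
        assert dag.graph.has_edge("A", "B")  # parsed, retained for rendering


class TestPropagation:
    def test_true_path_to_root(self, chain_dag):
        index = propagate_annotations(chain_dag, [("g", "T:0000003", "EXP")], ["g", "h"])
        assert index.annotated_genes("T:0000001") == {"g"}
        assert index.annotated_genes("T:0000002") == {"g"}

    def test_disjoint_branches_union_at_root(self):
        dag = make_dag([("L1", "R", "is_a"), ("L2", "R", "is_a")])
        index = propagate_annotations(
            dag, [("a", "L1", ""), ("b", "L2", ""), ("a", "L2", "")], ["a", "b"]
        )
        assert index.annotated_genes("R") == {"a", "b"}

    def test_unknown_term_dropped_with_warning(self, chain_dag, caplog):
        index = propagate_annotations(chain_dag, [("g", "T:9999999", "")], ["g"])
        assert index.propagated == {}

    def test_gene_outside_universe_rejected(self, chain_dag):
        with pytest.raises(ValueError, match="universe"):
            propagate_annotations(chain_dag, [("ghost", "T:0000003", "")], ["g"])

    def test_curated_only_drops_electronic_annotations(self, chain_dag):
        ann = [("g", "T:0000003", "IEA"), ("h", "T:0000003", "EXP")]
        index = propagate_annotations(chain_dag, ann, ["g", "h"], curated_only=True)
        assert index.annotated_genes("T:0000001") == {"h"}

    def test_matches_bruteforce_reachability_on_random_dags(self):
        rng = random.Random(13)
        for trial in range(20):
            n = rng.randint(4, 12)
            nodes = [f"N{i}" for i in range(n)]
            edges = []
            for i in range(1, n):
                parent = nodes[rng.randrange(i)]  # earlier node: acyclic
                edges.append((nodes[i], parent, rng.choice(["is_a", "part_of"])))
            dag = make_dag(edges)
            genes = [f"g{i}" for i in range(8)]
            annotations = [
                (rng.choice(genes), rng.choice(nodes), "") for _ in range(15)
            ]
            index = propagate_annotations(dag, annotations, genes)
            prop = dag.propagation_graph()
            # oracle: gene at term iff directly annotated to any term that reaches it
            for term in nodes:
                reachable_from = {term} | nx.ancestors(prop, term)
                expected = {g for g, t, _ in annotations if t in reachable_from}
                assert index.annotated_genes(term) == expected

    def test_monotone_child_to_parent(self, chain_dag):
        index = propagate_annotations(
            chain_dag, [("g", "T:0000003", ""), ("h", "T:0000002", "")], ["g", "h"]
        )
        assert index.annotated_genes("T:0000003") <= index.annotated_genes("T:0000002")
        assert index.annotated_genes("T:0000002") <= index.annotated_genes("T:0000001")


def fisher_oracle(a, n_set, k, n):
    """Exhaustive two-sided Fisher p: sum hypergeometric P(x) <= P(a)."""
    def pmf(x):
        return (
            math.comb(k, x) * math.comb(n - k, n_set - x) / math.comb(n, n_set)
        )

    p_obs = pmf(a)
    return sum(
        p
        for x in range(max(0, n_set - (n - k)), min(k, n_set) + 1)
        if (p := pmf(x)) <= p_obs * (1 + 1e-12)
    )


class TestRunORA:
    def _flat_index(self, term_genes, universe):
        dag = make_dag([(t, "ROOT", "is_a") for t in term_genes])
        ann = [(g, t, "") for t, genes in term_genes.items() for g in genes]
        return dag, propagate_annotations(dag, ann, universe)

    def test_enumerated_example(self):
        universe = [f"g{i}" for i in range(10)]
        dag, index = self._flat_index({"T1": universe[:5]}, universe)
        results = run_ora(universe[:4], index, ORAConfig(p_threshold=0.5), dag=dag)
        r = next(r for r in results if r.term_id == "T1")
        assert r.observed == 4
        assert r.expected == pytest.approx(2.0)
        assert r.p_value == pytest.approx(0.047619, abs=1e-6)

    def test_set_equals_universe_is_null(self):
        universe = [f"g{i}" for i in range(8)]
        dag, index = self._flat_index({"T1": universe[:4], "T2": universe[2:8]}, universe)
        for r in run_ora(universe, index, dag=dag):
            assert r.observed == r.annotated_in_universe
            assert r.observed == pytest.approx(r.expected)
            assert r.p_value == pytest.approx(1.0)
            assert r.direction == "none"

    def test_bonferroni_is_p_times_m_capped(self):
        universe = [f"g{i}" for i in range(12)]
        term_genes = {f"T{j}": universe[j : j + 4] for j in range(6)}
        dag, index = self._flat_index(term_genes, universe)
        results = run_ora(universe[:3], index, dag=dag)
        m = len(results)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * m))
            assert r.p_adjusted >= r.p_value

    def test_fisher_matches_enumeration_oracle(self):
        rng = random.Random(99)
        for _ in range(40):
            n = rng.randint(8, 60)
            universe = [f"g{i}" for i in range(n)]
            k = rng.randint(2, n - 1)
            n_set = rng.randint(1, n - 1)
            annotated = rng.sample(universe, k)
            gene_set = rng.sample(universe, n_set)
            dag, index = self._flat_index({"T1": annotated}, universe)
            results = run_ora(gene_set, index, ORAConfig(min_genes_per_term=2), dag=dag)
            r = next(r for r in results if r.term_id == "T1")
            a = len(set(annotated) & set(gene_set))
            assert r.p_value == pytest.approx(fisher_oracle(a, n_set, k, n), abs=1e-10)

    def test_min_genes_filter(self):
        universe = [f"g{i}" for i in range(10)]
        dag, index = self._flat_index({"T1": universe[:1], "T2": universe[:5]}, universe)
        tested = {r.term_id for r in run_ora(universe[:3], index, dag=dag)}
        assert "T1" not in tested  # only 1 annotated gene < min 2; ROOT and T2 pass

    def test_gene_outside_universe_rejected(self):
        universe = [f"g{i}" for i in range(6)]
        dag, index = self._flat_index({"T1": universe[:3]}, universe)
        with pytest.raises(ValueError, match="outside"):
            run_ora(["ghost"], index, dag=dag)

    def test_directions_partition_significant_terms(self):
        universe = [f"g{i}" for i in range(40)]
        term_genes = {"OVER": universe[:10], "UNDER": universe[10:36]}
        dag, index = self._flat_index(term_genes, universe)
        results = run_ora(universe[:10], index, ORAConfig(p_threshold=0.05), dag=dag)
        directions = {r.term_id: r.direction for r in results}
        assert directions["OVER"] == "over"
        assert directions["UNDER"] == "under"
        for r in results:
            assert (r.direction != "none") == (r.p_adjusted < 0.05)


class TestDagRoles:
    def _run(self, dag, term_genes, universe, gene_set, alpha=0.05):
        ann = [(g, t, "") for t, genes in term_genes.items() for g in genes]
        index = propagate_annotations(dag, ann, universe)
        results = run_ora(gene_set, index, ORAConfig(p_threshold=alpha), dag=dag)
        return annotate_dag_roles(results, dag, index)

    def test_single_significant_leaf_is_detail_and_headline(self):
        dag = make_dag([("LEAF", "MID", "is_a"), ("MID", "ROOT", "is_a")])
        universe = [f"g{i}" for i in range(30)]
        results, report = self._run(
            dag,
            {"LEAF": universe[:6], "MID": universe[6:20]},
            universe,
            universe[:6],
        )
        assert report.details == ["LEAF"]
        assert report.headlines == ["LEAF"]
        assert "detail" in report.node_classes["LEAF"]
        assert "headline" in report.node_classes["LEAF"]

    def test_no_significant_terms_all_structural(self, chain_dag):
        universe = [f"g{i}" for i in range(10)]
        ann = [(g, "T:0000003", "") for g in universe[:5]]
        index = propagate_annotations(chain_dag, ann, universe)
        results = run_ora(universe[:2], index, ORAConfig(p_threshold=0.001), dag=chain_dag)
        results, report = annotate_dag_roles(results, chain_dag, index)
        assert report.details == [] and report.headlines == []
        assert all(c == frozenset({"structural"}) for c in report.node_classes.values())

    def test_headline_maximizes_remarkableness_per_path(self):
        # diamond: D -> (M1, M2) -> R; enrichment planted deep at D
        dag = make_dag(
            [("D", "M1", "is_a"), ("D", "M2", "part_of"), ("M1", "R", "is_a"), ("M2", "R", "is_a")]
        )
        universe = [f"g{i}" for i in range(60)]
        term_genes = {"D": universe[:8], "M1": universe[:20], "M2": universe[:25]}
        results, report = self._run(dag, term_genes, universe, universe[:8])
        by = {r.term_id: r for r in results}
        sig = {t for t, r in by.items() if r.significant}
        assert "D" in report.details
        # oracle: exhaustive per-path maximization
        prop = dag.propagation_graph()
        expected_headlines = set()
        for path in nx.all_simple_paths(prop, "D", "R"):
            cands = [by[t] for t in path if t in sig]
            if cands:
                best = max(cands, key=lambda r: (r.remarkableness, -r.p_adjusted))
                expected_headlines.add(best.term_id)
        assert set(report.headlines) == expected_headlines

    def test_every_path_from_detail_has_headline(self):
        dag = make_dag(
            [("A", "B", "is_a"), ("B", "R", "is_a"), ("A", "C", "is_a"), ("C", "R", "is_a")]
        )
        universe = [f"g{i}" for i in range(40)]
        results, report = self._run(dag, {"A": universe[:7]}, universe, universe[:7])
        prop = dag.propagation_graph()
        headline_set = set(report.headlines)
        for detail in report.details:
            for path in nx.all_simple_paths(prop, detail, "R"):
                assert headline_set & set(path)


class TestExport:
    def test_dot_structure_and_determinism(self, chain_dag):
        universe = [f"g{i}" for i in range(20)]
        ann = [(g, "T:0000003", "") for g in universe[:5]]
        index = propagate_annotations(chain_dag, ann, universe)
        results = run_ora(universe[:5], index, ORAConfig(p_threshold=0.05), dag=chain_dag)
        results, report = annotate_dag_roles(results, chain_dag, index)
        dot1 = export_dag(report)
        dot2 = export_dag(report)
        assert dot1 == dot2
        assert dot1.count("fillcolor=") == 3  # one node line per term
        assert dot1.count(" -> ") == 2
        assert "gold" in dot1  # headline class present
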