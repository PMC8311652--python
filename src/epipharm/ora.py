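"""Over/under-representation analysis over an ontology DAG.

Gene-set function is summarized against an ontology (terms related by
``is_a`` / ``part_of`` / ``regulates`` edges forming a rooted DAG).  Direct
gene annotations are propagated upward along ``is_a`` and ``part_of`` edges
(true-path rule: a gene annotated to a term is annotated to all its
ancestors).  For every term with enough annotated genes, a two-sided Fisher
exact test on the 2x2 table (in set & annotated / in set & not / out of set
& annotated / neither) decides whether the study set contains more or fewer
annotated genes than a random set of the same size; Bonferroni correction
over the tested terms controls family-wise error.

Significant terms are then given structural roles for reporting: a *detail*
is a significant term none of whose descendants is significant (the tip of a
significant branch); on each path from a detail up to the root, the
significant term with the highest *remarkableness* — here
``(1 - p_adj) * IC`` with information content ``IC = -log2(K/N)`` — is the
branch's *headline*.  The scoring is pluggable via the ``score`` argument of
:func:`annotate_dag_roles`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

PROPAGATION_RELATIONS = ("is_a", "part_of")  # regulates parsed but not propagated

#: Evidence labels treated as non-curated (electronic annotation).
NON_CURATED_EVIDENCE = frozenset({"IEA"})


class OntologyError(ValueError):
    pass


@dataclass
class OntologyDag:
    """Ontology wrapper: ``graph`` has one edge child -> parent per relation.

    Only ``is_a`` and ``part_of`` edges participate in annotation
    propagation; the propagation subgraph must be acyclic.
    """

    graph: nx.MultiDiGraph

    def __post_init__(self) -> None:
        prop = self.propagation_graph()
        if not nx.is_directed_acyclic_graph(prop):
            cycle = nx.find_cycle(prop)
            raise OntologyError(f"ontology contains a cycle: {cycle}")

    def propagation_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        for child, parent, rel in self.graph.edges(keys=True):
            if rel in PROPAGATION_RELATIONS:
                g.add_edge(child, parent)
        return g

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", term_id)

    def namespace(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("namespace", "")

    def roots(self) -> list[str]:
        prop = self.propagation_graph()
        return sorted(n for n in prop.nodes if prop.out_degree(n) == 0)

    def depths(self) -> dict[str, int]:
        """Longest-path distance of each term from a root (root depth 0)."""
        prop = self.propagation_graph()
        depth: dict[str, int] = {}
        for node in reversed(list(nx.topological_sort(prop))):
            parents = list(prop.successors(node))
            depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth


def parse_ontology(source) -> OntologyDag:
    """Parse an OBO stream into an :class:`OntologyDag`.

    Stanzas marked obsolete are dropped (obonet convention); ``is_a`` and
    ``relationship:`` lines become typed edges; a cycle among
    ``is_a``/``part_of`` edges raises :class:`OntologyError`.
    """
    graph = obonet.read_obo(source, ignore_obsolete=True)
    return OntologyDag(graph=graph)


def write_obo(dag: OntologyDag, path: str | Path) -> None:
    """Serialize the DAG back to minimal OBO (deterministic ordering)."""
    lines = ["format-version: 1.2", ""]
    for term in dag.terms:
        data = dag.graph.nodes[term]
        lines += [
            "[Term]",
            f"id: {term}",
            f"name: {data.get('name', term)}",
        ]
        if data.get("namespace"):
            lines.append(f"namespace: {data['namespace']}")
        edges = sorted(dag.graph.edges(term, keys=True))
        for _, parent, rel in edges:
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# --- annotations -------------------------------------------------------------


@dataclass
class AnnotationIndex:
    """Direct and propagated gene annotations over a background universe."""

    direct: dict[str, frozenset[str]]  # term -> genes annotated directly
    propagated: dict[str, frozenset[str]]  # term -> genes after true-path rule
    universe: frozenset[str]

    def annotated_genes(self, term_id: str) -> frozenset[str]:
        return self.propagated.get(term_id, frozenset())


def read_annotations(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a (gene_id, term_id, evidence) annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return list(df[["gene_id", "term_id", "evidence"]].itertuples(index=False, name=None))


def propagate_annotations(
    dag: OntologyDag,
    annotations: Iterable[tuple[str, str, str]] | Mapping[str, Iterable[str]],
    universe: Iterable[str],
    curated_only: bool = False,
) -> AnnotationIndex:
    """Apply the true-path rule: each term inherits its descendants' genes.

    ``annotations`` is either (gene, term, evidence) triples or a mapping
    gene -> terms (evidence then unknown and kept regardless of
    ``curated_only``).  Annotations to terms absent from the ontology are
    dropped with a warning; an annotated gene outside the universe is an
    error.
    """
    universe_set = frozenset(universe)
    if isinstance(annotations, Mapping):
        triples = [(g, t, "") for g, terms in annotations.items() for t in terms]
    else:
        triples = list(annotations)
    direct: dict[str, set[str]] = {}
    for gene, term, evidence in triples:
        if curated_only and evidence in NON_CURATED_EVIDENCE:
            continue
        if term not in dag.graph.nodes:
            logger.warning("annotation to unknown term %s dropped", term)
            continue
        if gene not in universe_set:
            raise ValueError(f"annotated gene {gene!r} is not in the universe")
        direct.setdefault(term, set()).add(gene)
    prop_graph = dag.propagation_graph()
    propagated: dict[str, set[str]] = {t: set(direct.get(t, ())) for t in prop_graph.nodes}
    # children before parents: edges run child -> parent
    for node in nx.topological_sort(prop_graph):
        genes = propagated[node]
        for parent in prop_graph.successors(node):
            propagated[parent] |= genes
    return AnnotationIndex(
        direct={t: frozenset(g) for t, g in direct.items()},
        propagated={t: frozenset(g) for t, g in propagated.items() if g},
        universe=universe_set,
    )


# --- the test ----------------------------------------------------------------


@dataclass(frozen=True)
class ORAConfig:
    """Significance threshold, correction and term filters for the analysis."""

    p_threshold: float = 0.001
    min_genes_per_term: int = 2
    namespace: str | None = None
    curated_only: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_genes_per_term < 1:
            raise ValueError("min_genes_per_term must be >= 1")


@dataclass
class ORAResult:
    term_id: str
    name: str
    namespace: str
    observed: int
    expected: float
    annotated_in_universe: int
    p_value: float
    p_adjusted: float
    direction: str = "none"  # over | under | none
    is_detail: bool = False
    is_headline: bool = False
    remarkableness: float = 0.0

    @property
    def significant(self) -> bool:
        return self.direction != "none"


def run_ora(
    gene_set: Iterable[str],
    index: AnnotationIndex,
    config: ORAConfig = ORAConfig(),
    dag: OntologyDag | None = None,
) -> list[ORAResult]:
    """Two-sided Fisher exact ORA per term, Bonferroni-corrected.

    Tests every term with at least ``min_genes_per_term`` annotated universe
    genes (optionally restricted to one namespace, which requires ``dag``).
    Per term the 2x2 table counts set/non-set x annotated/non-annotated
    genes; expected = |set| * K / N; the correction factor m is the number
    of terms actually tested.
    """
    genes = frozenset(gene_set)
    universe = index.universe
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    outside = genes - universe
    if outside:
        raise ValueError(f"genes outside the universe: {sorted(outside)[:5]}")
    n_universe = len(universe)
    n_set = len(genes)
    tested: list[tuple[str, frozenset[str]]] = []
    for term in sorted(index.propagated):
        annotated = index.propagated[term] & universe
        if len(annotated) < config.min_genes_per_term:
            continue
        if config.namespace is not None:
            if dag is None:
                raise ValueError("namespace filtering requires the ontology DAG")
            if dag.namespace(term) != config.namespace:
                continue
        tested.append((term, annotated))
    m = len(tested)
    results: list[ORAResult] = []
    for term, annotated in tested:
        k = len(annotated)
        a = len(genes & annotated)
        b = n_set - a
        c = k - a
        d = n_universe - n_set - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        expected = n_set * k / n_universe
        p_adj = min(1.0, float(p) * m)
        direction = "none"
        if p_adj < config.p_threshold:
            if a > expected:
                direction = "over"
            elif a < expected:
                direction = "under"
        results.append(
            ORAResult(
                term_id=term,
                name=dag.name(term) if dag is not None else term,
                namespace=dag.namespace(term) if dag is not None else "",
                observed=a,
                expected=expected,
                annotated_in_universe=k,
                p_value=float(p),
                p_adjusted=p_adj,
                direction=direction,
            )
        )
    return results


def results_to_frame(results: Sequence[ORAResult]) -> pd.DataFrame:
    """Tabular export mirroring the standard ORA report columns."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "name": [r.name for r in results],
            "namespace": [r.namespace for r in results],
            "observed_annotations": [r.observed for r in results],
            "expected_annotations": [round(r.expected, 1) for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "direction": [r.direction for r in results],
            "is_detail": [r.is_detail for r in results],
            "is_headline": [r.is_headline for r in results],
            "remarkableness": [r.remarkableness for r in results],
        }
    )


# --- DAG roles ---------------------------------------------------------------


def default_remarkableness(result: ORAResult, index: AnnotationIndex) -> float:
    """(1 - p_adj) x information content, IC = -log2(K / N)."""
    k = result.annotated_in_universe
    n = len(index.universe)
    ic = -math.log2(k / n) if 0 < k < n else 0.0
    return (1.0 - result.p_adjusted) * ic


@dataclass
class DagReport:
    """Node classes for rendering: structural / over / under / detail / headline."""

    dag: OntologyDag
    node_classes: dict[str, frozenset[str]]
    details: list[str]
    headlines: list[str]


def annotate_dag_roles(
    results: Sequence[ORAResult],
    dag: OntologyDag,
    index: AnnotationIndex,
    score: Callable[[ORAResult, AnnotationIndex], float] = default_remarkableness,
) -> tuple[list[ORAResult], DagReport]:
    """Assign detail/headline roles and remarkableness to significant terms.

    A detail has no significant descendant.  For every simple path from a
    detail to a root (along is_a/part_of edges), the significant node
    maximizing the score is that path's headline; ties break toward smaller
    adjusted p, then greater depth.  Returns updated results plus the
    colored-DAG report.
    """
    by_term = {r.term_id: r for r in results}
    unknown = [t for t in by_term if t not in dag.graph.nodes]
    if unknown:
        raise ValueError(f"results reference terms absent from the DAG: {unknown[:5]}")
    prop = dag.propagation_graph()
    sig = {r.term_id for r in results if r.significant}
    for r in results:
        r.remarkableness = score(r, index) if r.significant else 0.0
        r.is_detail = False
        r.is_headline = False
    # descendants of t are nodes that reach t along child->parent edges
    details = sorted(t for t in sig if not (nx.ancestors(prop, t) & sig))
    depths = dag.depths()
    headlines: set[str] = set()
    roots = set(dag.roots())
    for detail in details:
        targets = (nx.descendants(prop, detail) | {detail}) & roots
        for root in sorted(targets):
            if detail == root:
                paths: Iterable[list[str]] = [[detail]]
            else:
                paths = nx.all_simple_paths(prop, detail, root)
            for path in paths:
                candidates = [by_term[t] for t in path if t in sig]
                if not candidates:
                    continue
                best = max(
                    candidates,
                    key=lambda r: (r.remarkableness, -r.p_adjusted, depths[r.term_id]),
                )
                headlines.add(best.term_id)
    for r in results:
        r.is_detail = r.term_id in details
        r.is_headline = r.term_id in headlines
    node_classes: dict[str, frozenset[str]] = {}
    for term in dag.terms:
        classes: set[str] = set()
        res = by_term.get(term)
        if res is not None and res.significant:
            classes.add("overrepresented" if res.direction == "over" else "underrepresented")
            if res.is_detail:
                classes.add("detail")
            if res.is_headline:
                classes.add("headline")
        else:
            classes.add("structural")
        node_classes[term] = frozenset(classes)
    report = DagReport(
        dag=dag,
        node_classes=node_classes,
        details=details,
        headlines=sorted(headlines),
    )
    return list(results), report


_FILL = {
    "headline": "gold",
    "detail": "lightblue",
    "overrepresented": "salmon",
    "underrepresented": "palegreen",
    "structural": "white",
}
_FILL_PRIORITY = ("headline", "detail", "overrepresented", "underrepresented", "structural")


def export_dag(report: DagReport) -> str:
    """Render the role-annotated DAG as a deterministic DOT document."""
    lines = ["digraph ontology {", "  rankdir=BT;", '  node [shape=ellipse, style=filled];']
    for term in report.dag.terms:
        classes = report.node_classes[term]
        fill = next(_FILL[c] for c in _FILL_PRIORITY if c in classes)
        border = (
            "red"
            if "overrepresented" in classes
            else "green" if "underrepresented" in classes else "black"
        )
        label = f"{report.dag.name(term)}\\n{term}"
        cls = ",".join(sorted(classes))
        lines.append(
            f'  "{term}" [label="{label}", fillcolor={fill}, color={border}, class="{cls}"];'
        )
    for child, parent, rel in sorted(report.dag.graph.edges(keys=True)):
        style = "solid" if rel in PROPAGATION_RELATIONS else "dashed"
        lines.append(f'  "{child}" -> "{parent}" [label="{rel}", style={style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
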