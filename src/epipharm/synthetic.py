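"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of a :class:`SyntheticSpec`: the same
seed yields byte-identical files.  Alongside the files, every generator
returns a *truth record* — the exact planted structure (interaction matrix,
per-year match schedule, enriched terms, accrual parameters) — which
downstream tests use as an independent oracle.

The defaults emulate the study conditions of the source analysis: a
68-enzyme registry with the published action mix, drugs with multi-group
membership and partially overlapping target lists, an ontology with planted
enrichment at odds ratio 8 for a 50-gene set over a 1000-gene universe, and
a publication corpus whose citations follow the saturating accrual
C(t) = N (1 - exp(-t/beta)) with the biochemistry constant beta = 5.4.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus import PublicationRecord, write_corpus
from .drugs import DrugRecord, TargetRecord, select_drugs, write_drug_database
from .registry import (
    ENZYME_ACTIONS,
    EnzymeRecord,
    EnzymeRegistry,
    load_reference_registry,
    write_registry_xml,
)

#: Enzyme-action composition of the published 68-enzyme drug-interacting set.
REFERENCE_ACTION_MIX: dict[str, int] = {
    "DNA methylation": 4,
    "DNA demethylation": 4,
    "histone methylation": 2,
    "histone demethylation": 1,
    "histone acetylation": 5,
    "histone deacetylation": 10,
    "histone ubiquitination": 2,
    "histone deubiquitination": 1,
    "histone phosphorylation": 30,
    "histone dephosphorylation": 3,
    "histone ADP-ribosylation": 3,
    "histone de-ADP-ribosylation": 1,
    "histone citrullination": 1,
    "histone biotinylation": 1,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """All sizes and planted structure for the generators; seed fixes everything."""

    seed: int = 0
    # registry
    n_enzymes: int = 68
    action_mix: Mapping[str, int] | None = None  # None -> reference mix, rescaled
    # drugs
    n_drugs: int = 60
    overlap_fraction: float = 0.3  # probability a target is a registry enzyme
    mean_targets_per_drug: float = 4.0
    dual_group_fraction: float = 0.15
    nonhuman_target_fraction: float = 0.1
    group_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "approved": 0.3,
            "investigational": 0.35,
            "experimental": 0.25,
            "nutraceutical": 0.03,
            "vet_approved": 0.04,
            "withdrawn": 0.03,
        }
    )
    # ontology
    n_terms: int = 120
    n_genes: int = 1000
    dag_depth: int = 4
    annotation_prob: float = 0.1
    planted_terms: int = 3
    planted_odds_ratio: float = 8.0
    set_size: int = 50
    iea_fraction: float = 0.2
    # corpus
    schedule: Mapping[int, int] | None = None  # year -> matching publications
    decoys_per_year: int = 3
    review_fraction: float = 0.2
    query_year: int = 2021
    beta: float = 5.4
    total_citations_mean: float = 60.0
    citation_noise: str = "none"  # none | poisson
    citations_by_year: Mapping[int, list[int]] | None = None
    country_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "United States": 0.45,
            "United Kingdom": 0.2,
            "Germany": 0.15,
            "Netherlands": 0.1,
            "China": 0.1,
        }
    )

    def __post_init__(self) -> None:
        for name in ("overlap_fraction", "dual_group_fraction", "nonhuman_target_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_enzymes, self.n_drugs, self.n_terms, self.n_genes) < 0:
            raise ValueError("sizes must be >= 0")


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    # one independent, process-stable stream per generator call
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([spec.seed, key]))


def _scaled_mix(spec: SyntheticSpec) -> list[str]:
    """Action labels for n_enzymes records, largest-remainder rescaling of the mix."""
    mix = dict(spec.action_mix) if spec.action_mix else dict(REFERENCE_ACTION_MIX)
    total = sum(mix.values())
    if spec.n_enzymes == 0 or total == 0:
        return []
    exact = {a: spec.n_enzymes * c / total for a, c in mix.items()}
    counts = {a: math.floor(v) for a, v in exact.items()}
    leftover = spec.n_enzymes - sum(counts.values())
    for a in sorted(mix, key=lambda a: (-(exact[a] - counts[a]), a))[:leftover]:
        counts[a] += 1
    labels: list[str] = []
    for action in ENZYME_ACTIONS:  # deterministic canonical order
        labels += [action] * counts.get(action, 0)
    return labels


def generate_enzyme_registry(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[EnzymeRegistry, dict]:
    """Write ``registry.xml``; truth lists every generated symbol and action."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = _scaled_mix(spec)
    records = [
        EnzymeRecord(
            gene_symbol=f"SYN{i + 1:04d}",
            gene_name=f"synthetic epigenetic enzyme {i + 1}",
            ncbi_gene_id=100000 + i,
            enzyme_action=action,
            uniprot_id=f"SP{i + 1:05d}",
        )
        for i, action in enumerate(labels)
    ]
    registry = EnzymeRegistry(records=records, source_label=f"synthetic-seed-{spec.seed}")
    write_registry_xml(registry, out_dir / "registry.xml")
    truth = {
        "n_enzymes": len(records),
        "actions": {r.gene_symbol: r.enzyme_action for r in records},
    }
    return registry, truth


def generate_drug_database(
    spec: SyntheticSpec, registry: EnzymeRegistry, out_dir: str | Path
) -> tuple[list[DrugRecord], dict]:
    """Write ``drugs.xml`` + ``uniprot_map.tsv``; truth holds the expected matrix.

    Targets mix registry genes (at ``overlap_fraction``) with decoy genes
    from a disjoint DECOY* namespace; some targets are non-human.  The truth
    record stores the exact drug x enzyme incidence expected after
    approved/investigational + human filtering.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, "drugs")
    groups, weights = zip(*sorted(spec.group_weights.items()))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    enzyme_symbols = registry.gene_symbols
    uniprot_of = {r.gene_symbol: r.uniprot_id or f"SPX{i:05d}" for i, r in enumerate(registry)}
    n_decoys = max(20, spec.n_drugs)
    for j in range(n_decoys):
        uniprot_of[f"DECOY{j + 1:04d}"] = f"SD{j + 1:05d}"
    decoy_symbols = [f"DECOY{j + 1:04d}" for j in range(n_decoys)]
    categories_pool = [
        "antineoplastic agents",
        "enzyme inhibitors",
        "kinase inhibitors",
        "histone deacetylase inhibitors",
        "nucleic acid synthesis inhibitors",
        "cytochrome P-450 substrates",
        "immunosuppressive agents",
        "anti-inflammatory agents",
        "antimetabolites",
        "protein kinase inhibitors",
    ]
    drugs: list[DrugRecord] = []
    for i in range(spec.n_drugs):
        gset = {str(rng.choice(groups, p=weights))}
        if rng.random() < spec.dual_group_fraction:
            gset.add(str(rng.choice(groups, p=weights)))
        n_cats = int(rng.integers(1, 4))
        cats = frozenset(rng.choice(categories_pool, size=n_cats, replace=False))
        n_targets = int(rng.poisson(spec.mean_targets_per_drug))
        chosen: set[str] = set()
        targets: list[TargetRecord] = []
        for _ in range(n_targets):
            if enzyme_symbols and rng.random() < spec.overlap_fraction:
                gene = str(rng.choice(enzyme_symbols))
            else:
                gene = str(rng.choice(decoy_symbols))
            if gene in chosen:
                continue
            chosen.add(gene)
            organism = "Mouse" if rng.random() < spec.nonhuman_target_fraction else "Humans"
            targets.append(
                TargetRecord(uniprot_id=uniprot_of[gene], organism=organism, gene_symbol=gene)
            )
        drugs.append(
            DrugRecord(
                drug_id=f"SB{i + 1:05d}",
                name=f"synthodrug-{i + 1:03d}",
                groups=frozenset(gset),
                categories=cats,
                targets=tuple(targets),
            )
        )
    write_drug_database(drugs, out_dir / "drugs.xml")
    id_map = pd.DataFrame(
        sorted((u, g) for g, u in uniprot_of.items()), columns=["uniprot_id", "gene_symbol"]
    )
    id_map.to_csv(out_dir / "uniprot_map.tsv", sep="\t", index=False)
    # bookkeeping: the matrix the pipeline must reproduce
    enzyme_set = set(enzyme_symbols)
    gene_of = {u: g for g, u in uniprot_of.items()}
    truth_cells: dict[str, list[str]] = {}
    for d in select_drugs(drugs):
        hits = sorted(
            {gene_of[t.uniprot_id] for t in d.targets if gene_of[t.uniprot_id] in enzyme_set}
        )
        if hits:
            truth_cells[d.name] = hits
    truth = {
        "matrix": truth_cells,
        "n_interacting_drugs": len(truth_cells),
        "n_interacting_enzymes": len({g for hits in truth_cells.values() for g in hits}),
        "total_interactions": sum(len(h) for h in truth_cells.values()),
    }
    return drugs, truth


def generate_ontology_with_annotations(
    spec: SyntheticSpec, out_dir: str | Path, universe: list[str] | None = None
) -> tuple[Path, Path, dict]:
    """Write ``ontology.obo`` + ``annotations.tsv``; truth lists planted terms.

    The DAG is rooted and layered: every term at depth d draws one ``is_a``
    parent from depth d-1 (plus an occasional ``part_of`` second parent).
    Baseline direct annotation is Bernoulli(``annotation_prob``) per
    (term, gene); at each planted term the designated gene set (the first
    ``set_size`` genes) is annotated at odds multiplied by
    ``planted_odds_ratio``.  Planted terms sit at maximal depth so their
    enrichment propagates only to their ancestors.

    ``universe`` overrides the synthesized gene names (``g00001``...) with an
    explicit list — e.g. the gene namespace of a generated drug database —
    so that ontology and drug fixtures can be wired together end to end.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, "ontology")
    n = spec.n_terms
    terms = [f"ST:{i:06d}" for i in range(n)]
    # assign depths: root at 0, remaining spread over 1..dag_depth
    depths = {terms[0]: 0}
    for i in range(1, n):
        depths[terms[i]] = 1 + (i - 1) % spec.dag_depth if spec.dag_depth > 1 else 1
    by_depth: dict[int, list[str]] = {}
    for t, d in depths.items():
        by_depth.setdefault(d, []).append(t)
    edges: list[tuple[str, str, str]] = []  # child, parent, relation
    for d in range(1, max(by_depth) + 1):
        parents_pool = by_depth.get(d - 1) or [terms[0]]
        for t in by_depth.get(d, []):
            parent = str(rng.choice(parents_pool))
            edges.append((t, parent, "is_a"))
            if len(parents_pool) > 1 and rng.random() < 0.2:
                second = str(rng.choice(parents_pool))
                if second != parent:
                    edges.append((t, second, "part_of"))
    obo_path = out_dir / "ontology.obo"
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    children = {c for c, _, _ in edges}
    for t in terms:
        lines += ["[Term]", f"id: {t}", f"name: synthetic term {t[3:]}",
                  "namespace: molecular_function"]
        for c, p, rel in edges:
            if c == t:
                lines.append(f"is_a: {p}" if rel == "is_a" else f"relationship: {rel} {p}")
        lines.append("")
    obo_path.write_text("\n".join(lines))
    # annotations
    if universe is not None:
        genes = list(universe)
        n_genes = len(genes)
    else:
        genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
        n_genes = spec.n_genes
    gene_set = genes[: spec.set_size]
    max_depth = max(by_depth)
    deepest = by_depth[max_depth]
    planted = sorted(str(t) for t in rng.choice(deepest, size=min(spec.planted_terms, len(deepest)), replace=False))
    p0 = spec.annotation_prob
    odds1 = spec.planted_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    evidence_pool = np.array(["EXP", "IDA", "IEA"])
    ev_weights = np.array([(1 - spec.iea_fraction) / 2, (1 - spec.iea_fraction) / 2,
                           spec.iea_fraction])
    rows = []
    planted_set = set(planted)
    for t in terms[1:]:  # root gets no direct annotation
        probs = np.full(n_genes, p0)
        if t in planted_set:
            probs[: spec.set_size] = p1
        mask = rng.random(n_genes) < probs
        for idx in np.nonzero(mask)[0]:
            ev = str(rng.choice(evidence_pool, p=ev_weights))
            rows.append((genes[idx], t, ev))
    ann_path = out_dir / "annotations.tsv"
    pd.DataFrame(rows, columns=["gene_id", "term_id", "evidence"]).to_csv(
        ann_path, sep="\t", index=False
    )
    truth = {
        "planted_terms": planted,
        "gene_set": gene_set,
        "universe": genes,
        "baseline_annotation_prob": p0,
        "planted_annotation_prob": p1,
        "odds_ratio": spec.planted_odds_ratio,
        "term_depths": {t: int(d) for t, d in depths.items()},
    }
    return obo_path, ann_path, truth


_MATCH_TEXT = (
    "epigenetic regulation of histone and DNA modification by deacetylase "
    "inhibition as a drug mechanism"
)
_DECOY_TEXTS = (
    "randomized clinical trial of antihypertensive therapy outcomes",
    "structural biology of membrane transporter conformations",
    "population pharmacokinetics of antibiotic dosing regimens",
)


def generate_publication_corpus(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[list[PublicationRecord], dict]:
    """Write ``corpus.tsv`` (+ population and national-output tables).

    Per scheduled year, the stated number of records carry query-matching
    text; ``decoys_per_year`` additional records do not (a
    ``review_fraction`` of decoys are typed Review).  Cumulative citations
    follow C = N (1 - exp(-dt/beta)) with per-paper totals N drawn
    exponentially around ``total_citations_mean`` (optionally
    Poisson-noised), unless ``citations_by_year`` pins exact values.  Truth
    stores the per-year match schedule and the planted (N, beta) values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, "corpus")
    schedule = dict(spec.schedule) if spec.schedule else {
        y: int(2 + 0.5 * (y - 1992)) for y in range(1992, 2021)
    }
    countries, cw = zip(*sorted(spec.country_weights.items()))
    cw = np.asarray(cw, dtype=float)
    cw = cw / cw.sum()
    records: list[PublicationRecord] = []
    planted_totals: dict[str, float] = {}
    rid = 0
    for year in sorted(schedule):
        dt = spec.query_year - year
        pinned = (spec.citations_by_year or {}).get(year)
        for j in range(schedule[year]):
            rid += 1
            if pinned is not None:
                cites = int(pinned[j % len(pinned)])
                n_total = float("nan")
            else:
                n_total = float(rng.exponential(spec.total_citations_mean))
                mean_c = n_total * (1 - math.exp(-dt / spec.beta)) if dt > 0 else 0.0
                cites = int(rng.poisson(mean_c)) if spec.citation_noise == "poisson" else int(
                    round(mean_c)
                )
            rec = PublicationRecord(
                record_id=f"PM{rid:06d}",
                year=year,
                country=str(rng.choice(countries, p=cw)),
                publication_types=frozenset({"Journal Article"}),
                text=_MATCH_TEXT,
                cumulative_citations=cites,
            )
            planted_totals[rec.record_id] = n_total
            records.append(rec)
        for _ in range(spec.decoys_per_year):
            rid += 1
            is_review = rng.random() < spec.review_fraction
            records.append(
                PublicationRecord(
                    record_id=f"PM{rid:06d}",
                    year=year,
                    country=str(rng.choice(countries, p=cw)),
                    publication_types=frozenset(
                        {"Review"} if is_review else {"Journal Article"}
                    ),
                    text=str(rng.choice(_DECOY_TEXTS)),
                    cumulative_citations=int(rng.poisson(5)),
                )
            )
    write_corpus(records, out_dir / "corpus.tsv")
    # denominator tables for country normalization
    years = sorted(schedule)
    pop_rows = []
    base_pop = {c: float(rng.integers(5, 350)) * 1e6 for c in countries}
    for c in countries:
        for y in years:
            pop_rows.append({"country": c, "year": y,
                             "population": base_pop[c] * (1 + 0.002 * (y - years[0]))})
    pd.DataFrame(pop_rows).to_csv(out_dir / "population.tsv", sep="\t", index=False)
    out_rows = [
        {"country": c, "publications": int(rng.integers(10_000, 2_000_000))}
        for c in countries
    ]
    pd.DataFrame(out_rows).to_csv(out_dir / "country_output.tsv", sep="\t", index=False)
    truth = {
        "schedule": {int(y): int(c) for y, c in schedule.items()},
        "beta": spec.beta,
        "query_year": spec.query_year,
        "planted_totals": planted_totals,
        "n_records": len(records),
    }
    return records, truth
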