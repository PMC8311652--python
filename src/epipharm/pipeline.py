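"""End-to-end orchestration of the four analysis stages.

Stage order: enzyme registry -> literature bibliometrics -> drug-database
interaction mining -> ontology over-representation analysis.  Each stage's
outputs (tables, counters) are collected in a :class:`ReportBundle` that can
be re-derived from the inputs and config; optional stages (e.g. no corpus
supplied) are skipped with a recorded notice.

The three ORA gene sets follow the study design: (i) all targets of
epigenetically interacting drugs, (ii) their epigenetic targets only, and
(iii) the set difference (their non-epigenetic targets), each tested against
the background of all targets of approved/investigational drugs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bibliometrics as bib
from . import corpus as cp
from . import drugs as dr
from . import ora
from .registry import (
    EnzymeRegistry,
    parse_enzyme_registry,
    read_registry_tsv,
    registry_summary,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    registry_path: str
    drugs_path: str | None = None
    id_map_path: str | None = None
    ontology_path: str | None = None
    annotations_path: str | None = None
    corpus_path: str | None = None
    population_path: str | None = None
    country_output_path: str | None = None
    query: str = cp.EPIGENETIC_DRUG_QUERY
    query_year: int = 2021
    betas: dict[str, float] = field(
        default_factory=lambda: {
            "biochemistry": bib.BETA_BIOCHEMISTRY,
            "pharmacology": bib.BETA_PHARMACOLOGY,
        }
    )
    allowed_groups: list[str] = field(default_factory=lambda: ["approved", "investigational"])
    category_min_count: int = 5
    ora: ora.ORAConfig = field(default_factory=ora.ORAConfig)
    out_dir: str = "epipharm_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ora_cfg = ora.ORAConfig(**raw.pop("ora", {}))
        return cls(ora=ora_cfg, **raw)

    def validate(self) -> None:
        if not Path(self.registry_path).exists():
            raise ConfigError(f"registry file not found: {self.registry_path}")
        for name in (
            "drugs_path",
            "id_map_path",
            "ontology_path",
            "annotations_path",
            "corpus_path",
            "population_path",
            "country_output_path",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} does not exist: {value}")


@dataclass
class ReportBundle:
    registry_summary: dict
    notices: list[str]
    trend: pd.DataFrame | None = None
    country_per_capita: pd.DataFrame | None = None
    country_per_output: pd.DataFrame | None = None
    matrix: dr.InteractionMatrix | None = None
    category_histogram: pd.DataFrame | None = None
    coverage: dict | None = None
    ora_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    dag_dot: str | None = None
    provenance: dict = field(default_factory=dict)


def _digest(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_registry(path: str) -> EnzymeRegistry:
    if path.endswith(".tsv"):
        return read_registry_tsv(path)
    return parse_enzyme_registry(path)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage for which inputs are configured."""
    config.validate()
    notices: list[str] = []
    registry = _load_registry(config.registry_path)
    logger.info("registry: %d enzymes", len(registry))
    bundle = ReportBundle(registry_summary=registry_summary(registry), notices=notices)

    # bibliometrics (optional)
    if config.corpus_path:
        records = cp.read_corpus(config.corpus_path)
        subset, per_year = cp.filter_corpus(records, config.query)
        models = [bib.CitationModel(beta=b, label=name) for name, b in config.betas.items()]
        bundle.trend = bib.citation_trend(subset, models, config.query_year)
        hits_by_country: dict[str, int] = {}
        for r in subset:
            hits_by_country[r.country] = hits_by_country.get(r.country, 0) + 1
        if config.population_path:
            pop = pd.read_csv(config.population_path, sep="\t")
            norm, warns = bib.normalize_country_counts(hits_by_country, pop, "per_capita")
            notices.extend(warns)
            bundle.country_per_capita = pd.DataFrame([vars(n) for n in norm])
        if config.country_output_path:
            out_tab = pd.read_csv(config.country_output_path, sep="\t")
            norm, warns = bib.normalize_country_counts(hits_by_country, out_tab, "per_output")
            notices.extend(warns)
            bundle.country_per_output = pd.DataFrame([vars(n) for n in norm])
        logger.info("corpus: %d records, %d matches", len(records), len(subset))
    else:
        notices.append("no corpus supplied: bibliometric stage skipped")

    # drug interactions (optional)
    selected: list[dr.DrugRecord] = []
    id_map: dict[str, str] = {}
    if config.drugs_path:
        all_drugs = dr.parse_drug_database(config.drugs_path)
        selected = dr.select_drugs(all_drugs, allowed_groups=set(config.allowed_groups))
        if config.id_map_path:
            id_map = (
                pd.read_csv(config.id_map_path, sep="\t")
                .set_index("uniprot_id")["gene_symbol"]
                .to_dict()
            )
        bundle.matrix = dr.build_interaction_matrix(selected, registry, id_map)
        bundle.category_histogram = dr.category_histogram(
            selected, min_count=config.category_min_count
        )
        bundle.coverage = dr.coverage_statistics(selected, bundle.matrix, registry)
        logger.info(
            "interactions: %d drugs x %d enzymes, %d cells",
            len(bundle.matrix.drug_names),
            len(bundle.matrix.enzyme_symbols),
            bundle.matrix.total_interactions,
        )
    else:
        notices.append("no drug database supplied: interaction stage skipped")

    # ORA (optional; needs interactions for the gene sets)
    if config.ontology_path and config.annotations_path:
        if bundle.matrix is None:
            notices.append("ORA skipped: needs the interaction stage for its gene sets")
        else:
            dag = ora.parse_ontology(config.ontology_path)
            annotations = ora.read_annotations(config.annotations_path)
            gene_of = dict(id_map)
            # background: all (mapped) targets of the selected drugs
            background: set[str] = set()
            interacting_drug_names = set(bundle.matrix.drug_names)
            epi_and_other: set[str] = set()
            for d in selected:
                for t in d.targets:
                    g = gene_of.get(t.uniprot_id) or t.gene_symbol
                    if g is None:
                        continue
                    background.add(g)
                    if d.name in interacting_drug_names:
                        epi_and_other.add(g)
            epigenetic = set(bundle.matrix.enzyme_symbols)
            gene_sets = {
                "all_targets": epi_and_other,
                "epigenetic_targets": epigenetic,
                "non_epigenetic_targets": epi_and_other - epigenetic,
            }
            annotated_genes = {g for g, _, _ in annotations}
            universe = background & annotated_genes if background else annotated_genes
            if len(universe) < 2:
                notices.append("ORA skipped: fewer than 2 background genes annotated")
            else:
                index = ora.propagate_annotations(
                    dag,
                    [(g, t, e) for g, t, e in annotations if g in universe],
                    universe,
                    curated_only=config.ora.curated_only,
                )
                for label, gs in gene_sets.items():
                    gs = gs & universe
                    if not gs:
                        notices.append(f"ORA set {label} empty after background restriction")
                        continue
                    results = ora.run_ora(gs, index, config.ora, dag=dag)
                    results, report = ora.annotate_dag_roles(results, dag, index)
                    bundle.ora_tables[label] = ora.results_to_frame(results)
                    if label == "all_targets":
                        bundle.dag_dot = ora.export_dag(report)
                logger.info("ORA: %d gene sets analysed", len(bundle.ora_tables))
    else:
        notices.append("no ontology/annotations supplied: ORA stage skipped")

    inputs = {
        name: _digest(path)
        for name, path in {
            "registry": config.registry_path,
            "drugs": config.drugs_path,
            "id_map": config.id_map_path,
            "ontology": config.ontology_path,
            "annotations": config.annotations_path,
            "corpus": config.corpus_path,
        }.items()
        if path
    }
    bundle.provenance = {"inputs_sha256": inputs, "query": config.query}
    return bundle


def write_reports(bundle: ReportBundle, out_dir: str | Path) -> list[str]:
    """Write the bundle's tables; returns the manifest of written files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _save(name: str, writer) -> None:
        writer(out / name)
        written.append(name)

    _save(
        "registry_summary.json",
        lambda p: p.write_text(json.dumps(bundle.registry_summary, indent=2) + "\n"),
    )
    if bundle.trend is not None:
        _save("citation_trend.tsv", lambda p: bundle.trend.to_csv(p, sep="\t", index=False))
    if bundle.country_per_capita is not None:
        _save(
            "country_per_capita.tsv",
            lambda p: bundle.country_per_capita.to_csv(p, sep="\t", index=False),
        )
    if bundle.country_per_output is not None:
        _save(
            "country_per_output.tsv",
            lambda p: bundle.country_per_output.to_csv(p, sep="\t", index=False),
        )
    if bundle.matrix is not None:
        _save("interaction_matrix.tsv", lambda p: bundle.matrix.to_tsv(p))
        marg = pd.DataFrame(
            {
                "axis": ["drug"] * len(bundle.matrix.drug_names)
                + ["enzyme"] * len(bundle.matrix.enzyme_symbols),
                "name": bundle.matrix.drug_names + bundle.matrix.enzyme_symbols,
                "interactions": list(bundle.matrix.row_marginals)
                + list(bundle.matrix.column_marginals),
            }
        )
        _save("interaction_marginals.tsv", lambda p: marg.to_csv(p, sep="\t", index=False))
    if bundle.category_histogram is not None:
        _save(
            "category_histogram.tsv",
            lambda p: bundle.category_histogram.to_csv(p, sep="\t", index=False),
        )
    if bundle.coverage is not None:
        _save(
            "coverage.json", lambda p: p.write_text(json.dumps(bundle.coverage, indent=2) + "\n")
        )
    for label, table in bundle.ora_tables.items():
        _save(f"ora_{label}.tsv", lambda p, t=table: t.to_csv(p, sep="\t", index=False))
    if bundle.dag_dot is not None:
        _save("ora_dag.dot", lambda p: p.write_text(bundle.dag_dot))
    manifest = {
        "files": written,
        "notices": bundle.notices,
        "provenance": bundle.provenance,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    written.append("manifest.json")
    return written
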