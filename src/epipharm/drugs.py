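"""Drug-database mining: parsing, group/organism filtering, and the
drug x epigenetic-enzyme interaction matrix.

Drug records follow the development-status grouping of pharmacological
databases (approved, investigational, experimental, illicit, nutraceutical,
vet_approved, withdrawn; a drug may hold several).  Only approved and
investigational drugs are analysed by default, their target lists restricted
to human proteins.  Targets are matched to registry enzymes via a
UniProt -> gene-symbol map, yielding a binary incidence matrix whose
marginals count interactions per drug and per enzyme.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .registry import EnzymeRegistry

logger = logging.getLogger(__name__)

DRUG_GROUPS = frozenset(
    {
        "approved",
        "investigational",
        "experimental",
        "illicit",
        "nutraceutical",
        "vet_approved",
        "withdrawn",
    }
)

DEFAULT_ALLOWED_GROUPS = frozenset({"approved", "investigational"})
HUMAN_ORGANISM = "Humans"

#: The epigenetic-enzyme genes among fostamatinib's published target list —
#: the drug with the most epigenetic interactions (20, all histone-substrate
#: kinases/enzymes) in the reference analysis.
FOSTAMATINIB_EPIGENETIC_GENES: tuple[str, ...] = (
    "AURKA", "AURKB", "AURKC", "CDK17", "CHEK1", "DAPK3", "FYN", "GSK3B",
    "JAK2", "LIMK2", "MAP3K12", "MAP3K20", "NEK9", "PAK1", "PAK2", "PKN1",
    "PRKAA1", "RPS6KA3", "STK10", "TLK1",
)


class DrugParseError(ValueError):
    pass


@dataclass(frozen=True)
class TargetRecord:
    """One molecular target of a drug, keyed by UniProt accession."""

    uniprot_id: str
    organism: str = HUMAN_ORGANISM
    gene_symbol: str | None = None
    ncbi_gene_id: int | None = None

    def __post_init__(self) -> None:
        if not self.uniprot_id:
            raise ValueError("uniprot_id must be non-empty")


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    groups: frozenset[str]
    categories: frozenset[str] = frozenset()
    targets: tuple[TargetRecord, ...] = ()

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError(f"drug {self.drug_id}: groups must be non-empty")
        unknown = self.groups - DRUG_GROUPS
        if unknown:
            raise ValueError(f"drug {self.drug_id}: unknown groups {sorted(unknown)}")


def parse_drug_database(source) -> list[DrugRecord]:
    """Parse drug XML (minimal DrugBank-v5-style dialect) into records.

    Layout: ``<drugs>`` root; per drug a ``<drug id=...>`` with ``<name>``,
    ``<groups><group>...``, ``<categories><category>...`` and
    ``<targets><target>`` children, each target holding ``<uniprot_id>``,
    ``<organism>`` and optional ``<gene_symbol>``/``<ncbi_gene_id>``.
    Drugs without an id are skipped with a warning.  The per-group counts
    (dual memberships counted in each group) are attached to the returned
    list as ``.group_counts`` via :func:`group_counts`.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise DrugParseError(f"malformed drug XML: {exc}") from exc
    records: list[DrugRecord] = []
    seen_ids: set[str] = set()
    for elem in tree.getroot().iter("drug"):
        drug_id = (elem.get("id") or "").strip()
        if not drug_id:
            logger.warning("drug element without id skipped")
            continue
        if drug_id in seen_ids:
            logger.warning("duplicate drug id %s skipped", drug_id)
            continue
        groups = frozenset(
            g.text.strip() for g in elem.findall("groups/group") if g.text
        )
        categories = frozenset(
            c.text.strip() for c in elem.findall("categories/category") if c.text
        )
        targets = []
        for t in elem.findall("targets/target"):
            uid = (t.findtext("uniprot_id") or "").strip()
            if not uid:
                logger.warning("drug %s: target without uniprot_id skipped", drug_id)
                continue
            ncbi_text = (t.findtext("ncbi_gene_id") or "").strip()
            targets.append(
                TargetRecord(
                    uniprot_id=uid,
                    organism=(t.findtext("organism") or HUMAN_ORGANISM).strip(),
                    gene_symbol=(t.findtext("gene_symbol") or "").strip() or None,
                    ncbi_gene_id=int(ncbi_text) if ncbi_text else None,
                )
            )
        records.append(
            DrugRecord(
                drug_id=drug_id,
                name=(elem.findtext("name") or drug_id).strip(),
                groups=groups,
                categories=categories,
                targets=tuple(targets),
            )
        )
        seen_ids.add(drug_id)
    return records


def write_drug_database(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    """Serialize drug records to the XML dialect read by :func:`parse_drug_database`."""
    root = ET.Element("drugs")
    for d in drugs:
        e = ET.SubElement(root, "drug", id=d.drug_id)
        ET.SubElement(e, "name").text = d.name
        groups = ET.SubElement(e, "groups")
        for g in sorted(d.groups):
            ET.SubElement(groups, "group").text = g
        cats = ET.SubElement(e, "categories")
        for c in sorted(d.categories):
            ET.SubElement(cats, "category").text = c
        targets = ET.SubElement(e, "targets")
        for t in d.targets:
            te = ET.SubElement(targets, "target")
            ET.SubElement(te, "uniprot_id").text = t.uniprot_id
            ET.SubElement(te, "organism").text = t.organism
            if t.gene_symbol:
                ET.SubElement(te, "gene_symbol").text = t.gene_symbol
            if t.ncbi_gene_id is not None:
                ET.SubElement(te, "ncbi_gene_id").text = str(t.ncbi_gene_id)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def group_counts(drugs: Iterable[DrugRecord]) -> dict[str, int]:
    """Per-group drug counts; dual memberships counted once per group."""
    counts: Counter[str] = Counter()
    for d in drugs:
        counts.update(d.groups)
    return dict(sorted(counts.items()))


def select_drugs(
    drugs: Sequence[DrugRecord],
    allowed_groups: frozenset[str] | set[str] = DEFAULT_ALLOWED_GROUPS,
    human_only: bool = True,
    human_label: str = HUMAN_ORGANISM,
) -> list[DrugRecord]:
    """Keep drugs with at least one allowed group; restrict targets to human.

    Organism comparison is exact but case-insensitive.  Drugs whose target
    list empties out are retained — they simply contribute no interactions.
    Idempotent.
    """
    out: list[DrugRecord] = []
    label = human_label.lower()
    for d in drugs:
        if not (d.groups & set(allowed_groups)):
            continue
        targets = d.targets
        if human_only:
            targets = tuple(t for t in targets if t.organism.lower() == label)
        out.append(replace(d, targets=targets))
    return out


@dataclass
class InteractionMatrix:
    """Binary drug x enzyme incidence with marginals.

    ``matrix`` is a 0/1 DataFrame indexed by drug name (rows, sorted) with
    enzyme gene symbols as columns (sorted); only drugs/enzymes with at
    least one interaction appear.
    """

    matrix: pd.DataFrame
    unmapped_targets: int = 0

    @property
    def drug_names(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def enzyme_symbols(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def row_marginals(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def column_marginals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def total_interactions(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t")


def build_interaction_matrix(
    drugs: Sequence[DrugRecord],
    registry: EnzymeRegistry,
    id_map: Mapping[str, str] | pd.DataFrame | None = None,
) -> InteractionMatrix:
    """Match drug targets to registry enzymes; cell (d, e) = 1 on interaction.

    Each target's gene is resolved through the UniProt -> gene-symbol map;
    a target with no map entry falls back to its own ``gene_symbol`` field,
    and is otherwise dropped (counted in ``unmapped_targets``).  Axes are
    restricted to drugs and enzymes with >= 1 interaction and sorted
    lexicographically for deterministic serialization.
    """
    if len(registry) == 0:
        raise ValueError("cannot match against an empty enzyme registry")
    if isinstance(id_map, pd.DataFrame):
        id_map = id_map.set_index("uniprot_id")["gene_symbol"].to_dict()
    id_map = dict(id_map or {})
    enzyme_set = set(registry.gene_symbols)
    pairs: set[tuple[str, str]] = set()
    unmapped = 0
    for d in drugs:
        for t in d.targets:
            gene = id_map.get(t.uniprot_id) or t.gene_symbol
            if gene is None:
                unmapped += 1
                continue
            if gene in enzyme_set:
                pairs.add((d.name, gene))
    if unmapped:
        logger.info("dropped %d targets with no gene mapping", unmapped)
    if not pairs:
        empty = pd.DataFrame(dtype=int)
        return InteractionMatrix(matrix=empty, unmapped_targets=unmapped)
    drug_names = sorted({p[0] for p in pairs})
    enzymes = sorted({p[1] for p in pairs})
    mat = pd.DataFrame(0, index=drug_names, columns=enzymes, dtype=int)
    for dname, gene in pairs:
        mat.at[dname, gene] = 1
    mat.index.name = "drug"
    return InteractionMatrix(matrix=mat, unmapped_targets=unmapped)


def category_histogram(
    drugs: Sequence[DrugRecord], min_count: int = 5
) -> pd.DataFrame:
    """Distinct-drug counts per category; categories below ``min_count`` suppressed."""
    counts: Counter[str] = Counter()
    for d in drugs:
        counts.update(d.categories)  # categories is a set: one count per drug
    rows = [
        {"category": c, "n_drugs": n}
        for c, n in counts.items()
        if n >= min_count
    ]
    df = pd.DataFrame(rows, columns=["category", "n_drugs"])
    return df.sort_values(["n_drugs", "category"], ascending=[False, True]).reset_index(
        drop=True
    )


@dataclass(frozen=True)
class ChiSquareResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float


def two_by_two_chi_square(
    table: Sequence[Sequence[float]], yates: bool = False
) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table (df = 1), upper-tail p.

    No continuity correction by default (``yates=True`` enables it).
    Both margins must be positive.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be >= 0")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    chi2, p, dof, _ = chi2_contingency(arr, correction=yates)
    return ChiSquareResult(chi_square=float(chi2), degrees_of_freedom=int(dof), p_value=float(p))


def percentage(part: float, whole: float, decimals: int = 2) -> float:
    """Reporting helper: 100 * part / whole rounded to ``decimals`` places."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round(100.0 * part / whole, decimals)


def coverage_statistics(
    drugs: Sequence[DrugRecord],
    matrix: InteractionMatrix,
    registry: EnzymeRegistry,
    all_drug_count: int | None = None,
    all_target_count: int | None = None,
) -> dict:
    """Summary counts and percentage shares of the interaction analysis."""
    stats = {
        "selected_drugs": len(drugs),
        "interacting_drugs": len(matrix.drug_names),
        "interacting_enzymes": len(matrix.enzyme_symbols),
        "registry_enzymes": len(registry),
        "total_interactions": matrix.total_interactions,
    }
    if all_drug_count:
        stats["interacting_drug_share_pct"] = percentage(
            len(matrix.drug_names), all_drug_count
        )
    if all_target_count:
        stats["enzyme_target_share_pct"] = percentage(
            len(matrix.enzyme_symbols), all_target_count
        )
    return stats
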