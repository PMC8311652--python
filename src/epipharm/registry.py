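"""Registry of enzymes that catalyze classical epigenetic reactions.

Classical epigenetic regulation acts at two substrates: the DNA itself
(methylation of cytosines and its removal) and the histone proteins around
which DNA is wrapped (acetylation, methylation, phosphorylation,
ubiquitination, ADP-ribosylation, citrullination, biotinylation and the
corresponding removal reactions).  Each registry record ties a human gene to
the single enzymatic action its product catalyzes, which is the unit that
drug targets are later matched against.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of enzymatic actions on the two epigenetic substrates.
ENZYME_ACTIONS: tuple[str, ...] = (
    "DNA methylation",
    "DNA demethylation",
    "histone methylation",
    "histone demethylation",
    "histone acetylation",
    "histone deacetylation",
    "histone ubiquitination",
    "histone deubiquitination",
    "histone phosphorylation",
    "histone dephosphorylation",
    "histone ADP-ribosylation",
    "histone de-ADP-ribosylation",
    "histone citrullination",
    "histone biotinylation",
)

_ACTION_SET = frozenset(ENZYME_ACTIONS)


class VocabularyError(ValueError):
    """An action label outside the closed enzyme-action vocabulary."""


class RegistryParseError(ValueError):
    """Structurally invalid registry XML."""


@dataclass(frozen=True)
class EnzymeRecord:
    """One epigenetic enzyme: HGNC-style gene symbol, name, ids and action."""

    gene_symbol: str
    gene_name: str
    ncbi_gene_id: int
    enzyme_action: str
    uniprot_id: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.ncbi_gene_id <= 0:
            raise ValueError("ncbi_gene_id must be positive")
        if self.enzyme_action not in _ACTION_SET:
            raise VocabularyError(
                f"unknown enzyme action {self.enzyme_action!r}; "
                f"accepted: {', '.join(ENZYME_ACTIONS)}"
            )

    @property
    def substrate(self) -> str:
        return classify_substrate(self.enzyme_action)


@dataclass
class EnzymeRegistry:
    """Ordered, duplicate-free collection of :class:`EnzymeRecord`."""

    records: list[EnzymeRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        symbols = [r.gene_symbol for r in self.records]
        if len(symbols) != len(set(symbols)):
            raise ValueError("duplicate gene symbols in registry")
        ids = [r.ncbi_gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate NCBI gene ids in registry")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_symbols(self) -> list[str]:
        return [r.gene_symbol for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "enzyme_action": [r.enzyme_action for r in self.records],
                "gene_name": [r.gene_name for r in self.records],
                "gene_symbol": [r.gene_symbol for r in self.records],
                "ncbi_gene_id": [r.ncbi_gene_id for r in self.records],
                "uniprot_id": [r.uniprot_id or "" for r in self.records],
            }
        )


def classify_substrate(action_label: str) -> str:
    """Map an enzyme-action label to its substrate class, ``DNA`` or ``histone``.

    Raises :class:`VocabularyError` for labels outside the closed vocabulary.
    """
    if action_label not in _ACTION_SET:
        raise VocabularyError(
            f"unknown enzyme action {action_label!r}; "
            f"accepted: {', '.join(ENZYME_ACTIONS)}"
        )
    return "DNA" if action_label.startswith("DNA") else "histone"


def parse_enzyme_registry(source) -> EnzymeRegistry:
    """Parse registry XML into an :class:`EnzymeRegistry`.

    The dialect is one ``<enzyme>`` element per record under a ``<registry>``
    root, with ``<gene_symbol>``, ``<gene_name>``, ``<ncbi_gene_id>``,
    ``<subclass>`` (the enzyme action) and optional ``<uniprot_id>`` children.
    Duplicate gene symbols are collapsed to the first occurrence with a logged
    warning; records missing a mandatory subclass are skipped and collected in
    the parse report attached as ``registry.parse_report``.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise RegistryParseError(f"malformed registry XML: {exc}") from exc
    root = tree.getroot()
    records: list[EnzymeRecord] = []
    seen: set[str] = set()
    seen_ids: set[int] = set()
    dropped_duplicates = 0
    record_errors: list[str] = []
    for elem in root.iter("enzyme"):
        symbol = (elem.findtext("gene_symbol") or "").strip()
        subclass = (elem.findtext("subclass") or "").strip()
        if not symbol:
            record_errors.append("enzyme element without gene_symbol skipped")
            continue
        if not subclass:
            record_errors.append(f"{symbol}: missing mandatory subclass")
            continue
        if symbol in seen:
            dropped_duplicates += 1
            logger.warning("duplicate enzyme %s dropped (first occurrence kept)", symbol)
            continue
        try:
            ncbi = int((elem.findtext("ncbi_gene_id") or "0").strip())
            if ncbi in seen_ids:
                record_errors.append(f"{symbol}: duplicate NCBI gene id {ncbi}")
                continue
            rec = EnzymeRecord(
                gene_symbol=symbol,
                gene_name=(elem.findtext("gene_name") or "").strip(),
                ncbi_gene_id=ncbi,
                enzyme_action=subclass,
                uniprot_id=(elem.findtext("uniprot_id") or "").strip() or None,
            )
        except (ValueError, VocabularyError) as exc:
            record_errors.append(f"{symbol}: {exc}")
            continue
        seen.add(symbol)
        seen_ids.add(ncbi)
        records.append(rec)
    registry = EnzymeRegistry(records=records, source_label=root.get("source", ""))
    registry.parse_report = {  # type: ignore[attr-defined]
        "parsed": len(records),
        "dropped_duplicates": dropped_duplicates,
        "record_errors": record_errors,
    }
    return registry


def write_registry_xml(registry: EnzymeRegistry, path: str | Path) -> None:
    """Serialize a registry to the XML dialect read by :func:`parse_enzyme_registry`."""
    root = ET.Element("registry", source=registry.source_label)
    for rec in registry.records:
        e = ET.SubElement(root, "enzyme")
        ET.SubElement(e, "gene_symbol").text = rec.gene_symbol
        ET.SubElement(e, "gene_name").text = rec.gene_name
        ET.SubElement(e, "ncbi_gene_id").text = str(rec.ncbi_gene_id)
        ET.SubElement(e, "subclass").text = rec.enzyme_action
        if rec.uniprot_id:
            ET.SubElement(e, "uniprot_id").text = rec.uniprot_id
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_registry_tsv(source) -> EnzymeRegistry:
    """Read a registry from a TSV with the enzyme-table column layout."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    records = [
        EnzymeRecord(
            gene_symbol=row["gene_symbol"],
            gene_name=row.get("gene_name", ""),
            ncbi_gene_id=int(row["ncbi_gene_id"]),
            enzyme_action=row["enzyme_action"],
            uniprot_id=row.get("uniprot_id") or None,
        )
        for row in df.fillna("").to_dict("records")
    ]
    return EnzymeRegistry(records=records, source_label="tsv")


def write_registry_tsv(registry: EnzymeRegistry, path: str | Path) -> None:
    registry.to_frame().to_csv(path, sep="\t", index=False)


def load_reference_registry() -> EnzymeRegistry:
    """The packaged 68-enzyme reference registry of drug-interacting epigenetic enzymes."""
    ref = resources.files("epipharm.data").joinpath("table2_enzymes.tsv")
    with ref.open("r") as fh:
        reg = read_registry_tsv(fh)
    reg.source_label = "packaged-reference"
    return reg


def registry_summary(registry: EnzymeRegistry) -> dict:
    """Per-action counts, substrate-class counts and the unique-enzyme count."""
    action_counts = {a: 0 for a in ENZYME_ACTIONS}
    substrate_counts = {"DNA": 0, "histone": 0}
    for rec in registry:
        action_counts[rec.enzyme_action] += 1
        substrate_counts[rec.substrate] += 1
    return {
        "unique_enzymes": len(set(registry.gene_symbols)),
        "per_action": action_counts,
        "per_substrate": substrate_counts,
    }


def summary_to_json(registry: EnzymeRegistry, path: str | Path) -> None:
    Path(path).write_text(json.dumps(registry_summary(registry), indent=2) + "\n")
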