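"""Boolean literature queries over a local publication corpus.

Implements a small search-engine-style query language: whole-token terms
with ``*`` prefix truncation, parenthesized boolean combinations with
precedence NOT > AND > OR (all left-associative, NOT binary as in
``A NOT B``), and the two field tags used in bibliographic searches —
``[PT]`` (publication type) and ``[PL]`` (place / country of the first
author's affiliation).  An empty query matches every record.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

FIELD_TAGS = ("PT", "PL")

#: The canonical epigenetic-drug-effects search string.  The historically
#: published form omits the final closing parenthesis (and contains the
#: misspelling "acethylase", preserved here); the closer is restored so the
#: string parses, which does not change its boolean meaning.
EPIGENETIC_DRUG_QUERY = (
    "(epigen* AND (histon* OR chromatin* OR DNA) "
    "AND (modificat* OR alterat* OR modulat* OR changes OR changing) "
    "AND (methylase OR demethylase OR acethylase OR deacetylase OR ubiquinase "
    "OR deubiquinase OR phosphorylase OR dephosphorylase OR sumoylase) "
    "AND ((drug OR pharmaceut*) NOT (review[PT])))"
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class QuerySyntaxError(ValueError):
    """Malformed query text; message carries the offending position."""


class QueryEvaluationError(ValueError):
    """A query referenced an unsupported field tag."""


@dataclass(frozen=True)
class PublicationRecord:
    """One literature item: id, year, country, types, free text, citations."""

    record_id: str
    year: int
    country: str = ""
    publication_types: frozenset[str] = frozenset()
    text: str = ""
    cumulative_citations: int = 0
    included: bool = True  # curation flag; filters may honor it

    def __post_init__(self) -> None:
        if self.cumulative_citations < 0:
            raise ValueError("cumulative_citations must be >= 0")

    @property
    def tokens(self) -> frozenset[str]:
        return frozenset(_TOKEN_RE.findall(self.text.lower()))


# --- query AST ---------------------------------------------------------------


@dataclass(frozen=True)
class QueryNode:
    """Node of the parsed query tree.

    ``kind`` is one of ``term``, ``field_term``, ``and``, ``or``, ``not``,
    ``all``.  Leaves carry ``token`` (lowercased) and ``wildcard``;
    ``field_term`` additionally carries ``tag``.  ``not`` is binary:
    left minus right.
    """

    kind: str
    token: str = ""
    tag: str = ""
    wildcard: bool = False
    children: tuple["QueryNode", ...] = ()

    def __str__(self) -> str:  # debugging aid
        if self.kind == "all":
            return "<all>"
        if self.kind in ("term", "field_term"):
            t = self.token + ("*" if self.wildcard else "")
            return f"{t}[{self.tag}]" if self.tag else t
        op = {"and": "AND", "or": "OR", "not": "NOT"}[self.kind]
        return "(" + f" {op} ".join(str(c) for c in self.children) + ")"


_LEX_RE = re.compile(
    r"""\s*(?:
        (?P<lpar>\()|(?P<rpar>\))|
        (?P<op>AND|OR|NOT)(?=[\s(])|
        (?P<quoted>"[^"]*")|
        (?P<word>[^\s()\[\]"]+)(?P<tag>\[[A-Za-z]+\])?
    )""",
    re.VERBOSE,
)


def _lex(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _LEX_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise QuerySyntaxError(f"cannot tokenize query at position {pos}")
        if m.group("lpar"):
            tokens.append(("(", "(", m.start()))
        elif m.group("rpar"):
            tokens.append((")", ")", m.start()))
        elif m.group("op"):
            tokens.append(("op", m.group("op"), m.start()))
        elif m.group("quoted") is not None:
            inner = m.group("quoted")[1:-1]
            # a quoted phrase with a trailing field tag, e.g. "review[PT]"
            tokens.append(("word", inner, m.start()))
        else:
            word = m.group("word")
            if m.group("tag"):
                word += m.group("tag")
            tokens.append(("word", word, m.start()))
        pos = m.end()
    return tokens


MATCH_ALL = QueryNode(kind="all")


def _leaf(word: str, pos: int) -> QueryNode:
    tag = ""
    m = re.search(r"\[([A-Za-z]+)\]$", word)
    if m:
        tag = m.group(1).upper()
        word = word[: m.start()]
    wildcard = word.endswith("*")
    token = word.rstrip("*").lower()
    if not token:
        raise QuerySyntaxError(f"empty term at position {pos}")
    kind = "field_term" if tag else "term"
    return QueryNode(kind=kind, token=token, tag=tag, wildcard=wildcard)


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query")
        self.i += 1
        return tok

    def parse_or(self) -> QueryNode:
        node = self.parse_and()
        while (tok := self.peek()) and tok[:2] == ("op", "OR"):
            self.next()
            rhs = self.parse_and()
            node = QueryNode(kind="or", children=(node, rhs))
        return node

    def parse_and(self) -> QueryNode:
        node = self.parse_not()
        while (tok := self.peek()) and tok[:2] == ("op", "AND"):
            self.next()
            rhs = self.parse_not()
            node = QueryNode(kind="and", children=(node, rhs))
        return node

    def parse_not(self) -> QueryNode:
        node = self.parse_atom()
        while (tok := self.peek()) and tok[:2] == ("op", "NOT"):
            self.next()
            rhs = self.parse_atom()
            node = QueryNode(kind="not", children=(node, rhs))
        return node

    def parse_atom(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("dangling operator at end of query")
        kind, value, pos = tok
        if kind == "(":
            self.next()
            node = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise QuerySyntaxError(f"unbalanced parenthesis opened at position {pos}")
            self.next()
            return node
        if kind == "word":
            self.next()
            return _leaf(value, pos)
        raise QuerySyntaxError(f"unexpected {value!r} at position {pos}")


def parse_query(text: str) -> QueryNode:
    """Parse query text into a :class:`QueryNode` tree.

    An empty (or all-whitespace) query yields the explicit match-all node,
    mirroring the empty-search-string convention of bibliographic engines.
    """
    if not text.strip():
        return MATCH_ALL
    tokens = _lex(text)
    if not tokens:
        return MATCH_ALL
    parser = _Parser(tokens)
    node = parser.parse_or()
    if parser.peek() is not None:
        kind, value, pos = parser.peek()
        raise QuerySyntaxError(f"unexpected {value!r} at position {pos}")
    return node


# --- evaluation --------------------------------------------------------------


def _match_token(token: str, wildcard: bool, candidates: Iterable[str]) -> bool:
    if wildcard:
        return any(c.startswith(token) for c in candidates)
    return token in candidates


def match_record(record: PublicationRecord, query: QueryNode) -> bool:
    """Evaluate a parsed query against one record.

    Plain terms match case-insensitively against whole tokens of the record
    text (prefix match when the wildcard flag is set); ``[PT]`` terms match
    the publication-type labels and ``[PL]`` terms the country, tokenized the
    same way.
    """
    k = query.kind
    if k == "all":
        return True
    if k == "term":
        return _match_token(query.token, query.wildcard, record.tokens)
    if k == "field_term":
        if query.tag == "PT":
            cands = {t.lower() for t in record.publication_types}
        elif query.tag == "PL":
            cands = set(_TOKEN_RE.findall(record.country.lower()))
            cands.add(record.country.lower())
        else:
            raise QueryEvaluationError(f"unknown field tag [{query.tag}]")
        return _match_token(query.token, query.wildcard, cands)
    if k == "and":
        return all(match_record(record, c) for c in query.children)
    if k == "or":
        return any(match_record(record, c) for c in query.children)
    if k == "not":
        left, right = query.children
        return match_record(record, left) and not match_record(record, right)
    raise QueryEvaluationError(f"unknown node kind {k!r}")


def filter_corpus(
    corpus: Sequence[PublicationRecord],
    query: QueryNode | str,
    honor_included_flag: bool = False,
) -> tuple[list[PublicationRecord], dict[int, int]]:
    """Return the matching subset (input order preserved) and per-year hit counts."""
    if isinstance(query, str):
        query = parse_query(query)
    subset = [
        r
        for r in corpus
        if match_record(r, query) and (r.included or not honor_included_flag)
    ]
    counts = Counter(r.year for r in subset)
    return subset, dict(sorted(counts.items()))


# --- corpus I/O ---------------------------------------------------------------

_COLUMNS = [
    "record_id",
    "year",
    "country",
    "publication_types",
    "text",
    "cumulative_citations",
    "included",
]


def read_corpus(path: str | Path) -> list[PublicationRecord]:
    """Read a corpus from TSV (``.tsv``) or JSON-lines (anything else)."""
    path = Path(path)
    records: list[PublicationRecord] = []
    if path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        rows = df.to_dict("records")
    else:
        rows = [json.loads(line) for line in path.read_text().splitlines() if line]
    for row in rows:
        types = row.get("publication_types", "")
        if isinstance(types, str):
            types = [t for t in types.split(";") if t]
        included = row.get("included", True)
        if isinstance(included, str):
            included = included.strip().lower() not in ("0", "false", "no", "")
        records.append(
            PublicationRecord(
                record_id=str(row["record_id"]),
                year=int(row["year"]),
                country=str(row.get("country", "")),
                publication_types=frozenset(types),
                text=str(row.get("text", "")),
                cumulative_citations=int(row.get("cumulative_citations", 0) or 0),
                included=bool(included),
            )
        )
    return records


def write_corpus(records: Iterable[PublicationRecord], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "record_id": r.record_id,
            "year": r.year,
            "country": r.country,
            "publication_types": ";".join(sorted(r.publication_types)),
            "text": r.text,
            "cumulative_citations": r.cumulative_citations,
            "included": r.included,
        }
        for r in records
    ]
    if path.suffix == ".tsv":
        pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        path.write_text("".join(json.dumps(row) + "\n" for row in rows))
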