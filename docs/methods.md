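# Methods

## Enzyme registry

A registry record ties one human gene (HGNC-style symbol, NCBI gene id,
optional UniProt accession) to exactly one enzymatic action from a closed
vocabulary of fourteen: two acting on DNA (methylation, demethylation) and
twelve on histones (methylation, demethylation, acetylation, deacetylation,
ubiquitination, deubiquitination, phosphorylation, dephosphorylation,
ADP-ribosylation, de-ADP-ribosylation, citrullination, biotinylation). The
substrate class (DNA vs histone) is derived from the action prefix, so
every record classifies to exactly one substrate.

The registry XML dialect is intentionally minimal — a `<registry>` root
with one `<enzyme>` element per record and `gene_symbol` / `gene_name` /
`ncbi_gene_id` / `subclass` / `uniprot_id` children — because the layouts
of the upstream enzyme archives vary and only these five fields feed the
analysis. Parsing is tolerant at the record level (a record missing its
mandatory subclass is skipped and reported; duplicates collapse to the
first occurrence with a warning) but strict at the document level
(malformed XML is an error). Gene symbols are validated structurally and
for uniqueness against the registry itself; no live nomenclature service is
consulted.

The packaged reference table (`data/table2_enzymes.tsv`) transcribes the
published 68-enzyme set of drug-interacting epigenetic enzymes, including
one row whose printed gene name and symbol disagree (peptidyl arginine
deiminase / PADI4); the transcription preserves the source verbatim. Its
composition — 8 DNA-substrate and 60 histone-substrate enzymes, dominated
by 30 histone-phosphorylating kinases and 10 deacetylases — also defines
the default action mix of the synthetic registry generator.

## Literature queries

The query language reimplements the observable core of a bibliographic
search engine: case-insensitive whole-token matching on title/abstract
text, `*` suffix for prefix truncation, `[PT]` matching publication-type
labels, `[PL]` matching the first-author country, parentheses, and the
operators NOT > AND > OR (left-associative; NOT is binary, `A NOT B` =
A ∧ ¬B). Tokenization splits on non-alphanumerics and lowercases — a
deterministic approximation; no stemming or controlled-vocabulary expansion
is attempted, so counts on real corpora will differ from a live engine's.
An empty query is an explicit match-all node, mirroring the empty-search-
string convention used to count a database's total content.

The packaged canonical search string for epigenetic drug effects preserves
the published token sequence (including the misspelling "acethylase") but
restores a missing closing parenthesis so the string parses; the addition
does not change its boolean meaning.

## Citation-expectation model

Citation accrual is modelled as C(t) = N·(1 − e^(−t/β)): an article
collects citations at a rate proportional to what it has yet to collect,
reaching 63 % of its eventual total N after β years. Inverting at the
observed cohort mean gives the expected total
⟨N̄cit⟩ = n̄cit,Δt / (1 − e^(−Δt/β)), which is always ≥ the observed mean,
decreasing in Δt and increasing in β. Δt is computed in whole years
(query year − publication year). Two β presets are shipped: 5.4 y
(biochemistry/molecular biology) and 7.1 y (pharmacology).

Reporting conventions: the exact cohort mean is kept internally; tabular
display truncates toward zero (a mean of 274.5 is reported as 274), while
the model is applied to the exact mean and its result rounded to the
nearest integer. `fit_beta` recovers (N, β) from an accrual series by
Levenberg–Marquardt least squares (scipy `curve_fit`, initialized at the
series maximum and mean time); series with fewer than three points or zero
range are rejected, non-monotone series fit with a warning.

Country normalization divides per-country hit counts by either the mean
population over the listed years (per-capita mode, long country/year/
population table) or the country's total publication output. Countries
without a usable denominator are excluded with a warning rather than
failing the run, since denominator tables are routinely incomplete.

## Drug-interaction mining

The drug XML dialect is a minimal subset of the DrugBank v5 layout: per
drug an id, name, development-status groups (a drug may hold several —
dual approved/investigational membership is common and preserved),
free-text categories, and targets carrying a UniProt accession, organism,
and optional gene symbol. Selection keeps drugs with at least one allowed
group (default: approved, investigational) and restricts target lists to
the configured organism label (default "Humans", compared
case-insensitively); drugs whose target lists empty out are retained and
simply contribute no interactions, making selection idempotent.

Matrix construction resolves each target to a gene through the
UniProt→gene map; a target absent from the map falls back to its own
`gene_symbol` field (this lets printed gene lists be used directly as
fixtures), and is otherwise dropped and counted. Cell (d, e) is 1 iff drug
d has a resolved target among the registry's enzymes. Axes are restricted
to drugs/enzymes with at least one interaction and sorted
lexicographically, making serialization deterministic; the total equals
both marginal sums by construction.

The 2×2 test is Pearson's χ² without continuity correction (df = 1), with
a flag for the Yates correction; both margins must be positive. Percentage
reporting is `round(100·part/whole, decimals)` with two decimals by
default, matching the conventions of the coverage summaries (82/2914 →
2.81 %, 15/7213 at one decimal → 0.2 %).

## Over-representation analysis

Ontology parsing (via obonet) accepts OBO 1.2 stanzas; obsolete terms are
dropped, `is_a` and `part_of` edges form the propagation DAG (checked
acyclic), and `regulates` edges are parsed and rendered but never
propagated, following standard true-path practice. Propagation runs one
topological sweep, child before parent, so each term's gene set is its
direct genes united with all descendants' sets; this matches brute-force
reachability by construction and is verified against it in tests.

Per term with ≥ `min_genes_per_term` (default 2) annotated universe genes
— optionally restricted to one namespace and to curated evidence (the
`curated_only` flag drops IEA-labelled annotation rows) — the 2×2 table
(set∩annotated, set∖annotated, annotated∖set, neither) is tested with the
two-sided Fisher exact test (scipy), whose two-sided p sums all
hypergeometric outcomes no more probable than the observed table.
Expected = |set|·K/N. Bonferroni multiplies by m = the number of terms
actually tested (after all filters) and caps at 1; a term is significant
when p_adj < the threshold (default 0.001) and is directed *over* or
*under* by comparing observed against expected.

Role assignment: details are significant terms with no significant
descendant. Remarkableness combines certainty and information value as
R = (1 − p_adj)·IC with IC = −log₂(K/N); the authoritative scoring for
headline selection lives in prior literature not restated here, so R is a
documented stand-in behind a pluggable `score` callable. For every simple
path from a detail to a root, the significant node maximizing R (ties:
smaller p_adj, then greater depth, depth being the longest distance from a
root) is that path's headline; since the detail itself is significant,
every such path carries at least one headline. Path enumeration is
exhaustive and therefore exponential in pathological multi-parent DAGs;
the intended inputs (ontology neighbourhoods of a result set) are small.
DOT export emits one node per term with fill colour by role priority
(headline > detail > over > under > structural) and border colour by
direction, in sorted order, so identical reports yield byte-identical
documents.

## Synthetic data

Each generator draws from its own `numpy` Generator seeded by
(seed, CRC32 of the generator name), so generators are independent and
byte-reproducible; no global random state is touched.

*Registry*: symbols `SYNnnnn` with the reference action mix rescaled by
largest remainder (at n = 68 this reproduces the published composition
exactly). *Drugs*: groups drawn from a weighted mix (approved 0.30,
investigational 0.35, experimental 0.25, remainder minor groups; 15 % dual
membership), Poisson(4) targets per drug, each a registry gene with
probability `overlap_fraction` (default 0.3) or else a decoy from the
disjoint `DECOY*` namespace, 10 % of targets non-human. The truth record
stores the exact post-filter interaction matrix. *Ontology*: a layered
rooted DAG (default 120 terms, depth 4; each term one `is_a` parent from
the previous layer, 20 % chance of a second `part_of` parent). Direct
annotation is Bernoulli(0.1) per (term, gene) — giving each gene ≈ 12
direct annotations over the default ontology, comparable to real per-gene
annotation counts — and at each planted term (placed at maximal depth) the
designated gene set's annotation odds are multiplied by the planted odds
ratio (default 8, set 50, universe 1000). At these densities the planted
term is recovered after Bonferroni at 0.001 in ≳ 95 % of seeded
replicates, which the acceptance suite measures over 100 runs.
*Corpus*: per scheduled year the stated number of records carry text
satisfying the canonical search string, plus non-matching decoys (20 %
reviews); citations follow the accrual curve with per-paper totals drawn
exponentially (mean 60) and optional Poisson noise, or exact pinned values
for worked-example cohorts.

What the generators do not emulate: realistic marginal distributions of
real literature or drug databases (vocabulary size, category co-occurrence,
citation heavy tails), annotation evidence-code semantics beyond the
curated/electronic split, and any engine-side query normalization. Passing
tests therefore demonstrate correctness of the computations on inputs with
known structure, not calibration against live database snapshots — whose
printed totals (hit counts, drug counts, per-term ORA numbers) are
version-dependent and out of scope.

## Problem sizes and runtime

The test suite runs the full property checks at small scale: query
equivalence on 20–40-record corpora over 40–50 random queries, Fisher
enumeration up to universe 60, propagation oracles on ≤ 15-node DAGs,
100 ORA replicates at the default 120-term/1000-gene configuration, and
five random drug-database specs. The complete suite finishes in about a
minute on one CPU; the acceptance script runs in seconds.

## Known limitations

- The boolean engine approximates, not replicates, a production search
  engine; absolute hit counts on real corpora are not comparable.
- The χ² behind the published underrepresentation claim depends on a 2×2
  table that is not recoverable from printed counts; the package provides
  the conventional Pearson test rather than asserting that statistic.
- Headline selection scores are a documented stand-in (see above) and
  pluggable; coverage/conciseness criteria beyond per-path maximization
  are not implemented.
- Δt in whole years makes the expectation model coarse for cohorts
  published mid-year.
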