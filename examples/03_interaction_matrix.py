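"""Mining a drug database for epigenetic-enzyme interactions.

Generates a synthetic drug database against the 68-enzyme reference
registry, filters to approved/investigational drugs with human targets,
builds the binary interaction matrix, and demonstrates the 2x2 chi-square
used to test over/underrepresentation of drug classes.
"""

import tempfile
from pathlib import Path

import pandas as pd

import epipharm as ep
from epipharm.drugs import FOSTAMATINIB_EPIGENETIC_GENES
from epipharm.synthetic import SyntheticSpec, generate_drug_database

registry = ep.load_reference_registry()
spec = SyntheticSpec(seed=7, n_drugs=40, overlap_fraction=0.0)  # decoy-only background

with tempfile.TemporaryDirectory() as d:
    drugs, truth = generate_drug_database(spec, registry, d)
    id_map = pd.read_csv(Path(d) / "uniprot_map.tsv", sep="\t")

# add a fostamatinib-style record: the published 20 epigenetic targets + decoys
fosta = ep.DrugRecord(
    drug_id="DB12010",
    name="fostamatinib",
    groups=frozenset({"approved"}),
    targets=tuple(
        ep.TargetRecord(uniprot_id=f"U{i}", gene_symbol=g)
        for i, g in enumerate(FOSTAMATINIB_EPIGENETIC_GENES + tuple(f"DECOY{i}" for i in range(30)))
    ),
)
selected = ep.select_drugs(list(drugs) + [fosta])
matrix = ep.build_interaction_matrix(selected, registry, id_map)

print(f"interaction matrix: {len(matrix.drug_names)} drugs x "
      f"{len(matrix.enzyme_symbols)} enzymes, {matrix.total_interactions} interactions")
print(f"fostamatinib row marginal: {matrix.row_marginals['fostamatinib']}")
print(f"busiest enzymes: {matrix.column_marginals.sort_values(ascending=False).head(3).to_dict()}")

# 2x2 chi-square: do epigenetically interacting drugs make up a smaller share
# of one group than another?  (illustrative counts)
result = ep.two_by_two_chi_square([[10, 90], [20, 80]])
print(f"chi-square = {result.chi_square:.4f}, df = {result.degrees_of_freedom}, "
      f"p = {result.p_value:.4f}")

# fostamatinib matches exactly its 20 published epigenetic-enzyme genes; the
# decoy targets fall outside the registry and contribute no interactions.
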