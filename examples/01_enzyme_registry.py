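"""The packaged registry of drug-interacting epigenetic enzymes.

Loads the 68-enzyme reference table, summarizes it per enzymatic action and
per substrate class, and shows the DNA/histone dichotomy.
"""

import json

import epipharm as ep

registry = ep.load_reference_registry()
summary = ep.registry_summary(registry)

print(f"enzymes: {summary['unique_enzymes']}")
print(f"substrate classes: {summary['per_substrate']}")
print("largest action classes:")
for action, n in sorted(summary["per_action"].items(), key=lambda kv: -kv[1])[:4]:
    print(f"  {action:28s} {n}")

print()
print("HDAC1 acts by", next(r.enzyme_action for r in registry if r.gene_symbol == "HDAC1"),
      "->", ep.classify_substrate("histone deacetylation"), "substrate")

# The 68 enzymes split 8 DNA-substrate vs 60 histone-substrate; histone
# phosphorylation (30 kinases) dominates because many approved kinase
# inhibitors hit histone-phosphorylating enzymes among their targets.
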