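"""Summarize subfamily spread across a taxonomy and annotate a tree.

Counts are aggregated up the lineage tree; a subfamily is trans-kingdom
when it appears under at least two children of the root.  The tree
annotation uses the fixed colour convention GXGCP→yellow, XTCD→blue.
"""

import tempfile
from pathlib import Path

from csab import (
    GeneratorConfig,
    classify,
    generate_corpus,
    spread_by_clade,
    synthetic_lineage_table,
    synthetic_taxonomy_newick,
    trans_kingdom_flag,
    trim_to_mature,
    write_tree_annotation,
)

records, _ = generate_corpus(GeneratorConfig(n_gxgcp=88, n_xtcd=35, seed=1))
calls = [classify(trim_to_mature(r)) for r in records]

root, unplaced = spread_by_clade(calls, synthetic_lineage_table())
for kingdom, node in sorted(root.children.items()):
    print(f"{kingdom}: {dict(node.total())} -> {node.status()}")
print("trans-kingdom GXGCP:", trans_kingdom_flag(root, "GXGCP"))
print("trans-kingdom XTCD: ", trans_kingdom_flag(root, "XTCD"))

with tempfile.TemporaryDirectory() as tmp:
    per_taxon = {}
    for call in calls:
        if call.label in ("GXGCP", "XTCD"):
            per_taxon.setdefault(call.taxon_id, set()).add(call.label)
    result = write_tree_annotation(synthetic_taxonomy_newick(), per_taxon, tmp)
    print("\ntree annotation:")
    print(Path(result["annotation"]).read_text())
# GXGCP peptides occur under both Bacteria and Eukaryota (trans-kingdom);
# XTCD peptides are confined to the recent insect orders.
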