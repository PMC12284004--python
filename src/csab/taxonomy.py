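"""Subfamily spread across a supplied taxonomy.

Aggregates per-peptide subfamily calls up a lineage tree (root→leaf clade
paths from a :class:`~csab.io_formats.LineageTable`) and asks the
headline biogeographic question: is a subfamily *trans-kingdom*, i.e.
found under at least two of the root's immediate children?  "Kingdom" is
operationalised as depth-1 of the supplied lineages (e.g. Bacteria and
Eukaryota under a shared root), keeping the module fully offline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import LineageTable
from .subfamily import GXGCP, XTCD, SubfamilyCall


@dataclass
class TaxonSummary:
    """One clade: its own calls plus recursively aggregated child counts."""

    name: str
    depth: int
    own: Counter = field(default_factory=Counter)
    children: dict[str, "TaxonSummary"] = field(default_factory=dict)

    def total(self) -> Counter:
        counts = Counter(self.own)
        for child in self.children.values():
            counts.update(child.total())
        return counts

    def status(self) -> str:
        counts = self.total()
        has_g, has_x = counts.get(GXGCP, 0) > 0, counts.get(XTCD, 0) > 0
        if has_g and has_x:
            return "mixed"
        if has_g:
            return "GXGCP-only"
        if has_x:
            return "XTCD-only"
        return "none"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "depth": self.depth,
            "status": self.status(),
            "counts": dict(sorted(self.total().items())),
            "children": [
                self.children[name].to_dict() for name in sorted(self.children)
            ],
        }


def spread_by_clade(
    calls: Iterable[SubfamilyCall], lineages: LineageTable
) -> tuple[TaxonSummary, list[str]]:
    """Aggregate subfamily calls up the lineage tree.

    Returns the root summary and the ids of peptides whose taxon is
    missing from the table (the "unplaced" bin); order of the input calls
    never affects the result.
    """
    root_name = lineages.root or "Root"
    root = TaxonSummary(name=root_name, depth=0)
    unplaced: list[str] = []
    for call in calls:
        if call.taxon_id is None or call.taxon_id not in lineages:
            unplaced.append(call.peptide_id)
            continue
        lineage = lineages.lineage(call.taxon_id)
        node = root
        for depth, clade in enumerate(lineage[1:], start=1):
            node = node.children.setdefault(
                clade, TaxonSummary(name=clade, depth=depth)
            )
        node.own[call.label] += 1
    unplaced.sort()
    return root, unplaced


def trans_kingdom_flag(summary: TaxonSummary, label: str) -> bool:
    """True iff ``label`` occurs under ≥ 2 distinct depth-1 clades."""
    kingdoms = sum(
        1 for child in summary.children.values() if child.total().get(label, 0) > 0
    )
    return kingdoms >= 2
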