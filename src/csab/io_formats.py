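"""Reading and writing the pipeline's external representations.

Formats handled here: protein FASTA (in/out, wrapped at 60 columns on
write, any wrap accepted on read), aligned FASTA (out), lineage TSV (in),
Newick taxonomy (pass-through), and the TSV/JSON report files the other
modules emit.

All residue positions surfaced to users are 1-based; internal indices are
0-based and never leave the module boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical amino-acid alphabet plus X (unknown). X never matches a motif.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

#: Fixed subfamily → colour bijection used for tree annotation.
SUBFAMILY_COLOURS = {"GXGCP": "yellow", "XTCD": "blue"}


class FastaParseError(ValueError):
    """Raised when a FASTA file is syntactically malformed."""


class RecordValidationError(ValueError):
    """Raised when a record violates an invariant (alphabet, uniqueness)."""


@dataclass
class PeptideRecord:
    """A single candidate CSαβ peptide (precursor or mature).

    Attributes
    ----------
    id : unique identifier within a collection.
    sequence : uppercase amino-acid string over the 20 canonical letters
        plus ``X``.
    description : free text from the FASTA header.
    taxon_id : optional key into a :class:`LineageTable`.
    lineage : optional root→leaf list of clade names.
    """

    id: str
    sequence: str
    description: str = ""
    taxon_id: str | None = None
    lineage: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordValidationError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise RecordValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise RecordValidationError(
                f"record {self.id!r}: illegal residue letter(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LineageTable:
    """Per-taxon ordered lineages (root→leaf) with display names.

    Stands in for a live taxonomy service: lineages are supplied as a TSV
    and must all start at the same root clade.
    """

    rows: dict[str, tuple[tuple[str, ...], str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = {lineage[0] for lineage, _ in self.rows.values() if lineage}
        if len(roots) > 1:
            raise RecordValidationError(
                f"lineages disagree on the root clade: {sorted(roots)}"
            )

    @property
    def root(self) -> str | None:
        for lineage, _ in self.rows.values():
            if lineage:
                return lineage[0]
        return None

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.rows

    def __len__(self) -> int:
        return len(self.rows)

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        return self.rows[taxon_id][0]

    def name(self, taxon_id: str) -> str:
        return self.rows[taxon_id][1]


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read a protein FASTA into :class:`PeptideRecord` objects.

    Sequences are uppercased and a single terminal ``*`` stop is stripped.
    Duplicate ids and illegal residue letters are rejected.
    """
    path = Path(path)
    # Cheap pre-scan so a malformed header error can name its line.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected a '>' header, "
                        f"got {line.strip()[:30]!r}"
                    )
                break
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise RecordValidationError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        # a "taxon=<id>" token in the description carries the taxon through
        # FASTA round-trips
        taxon_id = None
        for token in rec.description.split():
            if token.startswith("taxon="):
                taxon_id = token[len("taxon="):]
        records.append(
            PeptideRecord(
                id=rec.id, sequence=seq, description=rec.description,
                taxon_id=taxon_id,
            )
        )
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            handle.write(f">{header}\n")
            for start in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[start : start + width] + "\n")


def write_aligned_fasta(ids: Sequence[str], rows: Sequence[str], path: str | Path) -> None:
    """Write gapped rows as aligned FASTA (one wrap-free line per row)."""
    seq_records = [SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(ids, rows)]
    with open(path, "w") as handle:
        for rec in seq_records:
            handle.write(f">{rec.id}\n{rec.seq}\n")


def read_lineage_tsv(path: str | Path) -> LineageTable:
    """Read a lineage TSV with columns ``taxon_id``, ``lineage``, ``name``.

    The lineage column holds semicolon-joined clade names, root first.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FastaParseError(f"{path}: empty lineage file") from exc
    missing = {"taxon_id", "lineage", "name"} - set(table.columns)
    if missing:
        raise FastaParseError(f"{path}: missing column(s) {sorted(missing)}")
    rows: dict[str, tuple[tuple[str, ...], str]] = {}
    for _, row in table.iterrows():
        taxon_id = str(row["taxon_id"]).strip()
        if taxon_id in rows:
            raise RecordValidationError(f"{path}: duplicate taxon_id {taxon_id!r}")
        lineage = tuple(
            part.strip() for part in str(row["lineage"]).split(";") if part.strip()
        )
        rows[taxon_id] = (lineage, str(row["name"]).strip())
    return LineageTable(rows=rows)


def newick_leaf_names(newick: str) -> list[str]:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]


def write_tree_annotation(
    newick: str,
    calls: Mapping[str, str | Iterable[str]],
    out_dir: str | Path,
) -> dict[str, Path | list[str]]:
    """Emit the taxonomy tree plus a per-leaf subfamily colour table.

    Writes the unchanged Newick (``tree.nwk``), an annotation TSV
    ``tree_annotation.tsv`` with columns leaf/label/colour using the fixed
    mapping GXGCP→yellow, XTCD→blue (a taxon with both labels gets both
    rows), and a ``skipped_leaves.txt`` report for labels whose taxon is
    not a leaf of the tree. Missing leaves are a warning, never fatal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    leaves = set(newick_leaf_names(newick))

    tree_path = out_dir / "tree.nwk"
    tree_path.write_text(newick if newick.endswith("\n") else newick + "\n")

    skipped: list[str] = []
    lines = ["leaf\tlabel\tcolour"]
    for taxon in sorted(calls):
        labels = calls[taxon]
        if isinstance(labels, str):
            labels = [labels]
        if taxon not in leaves:
            skipped.append(taxon)
            continue
        for label in sorted(set(labels)):
            if label in SUBFAMILY_COLOURS:
                lines.append(f"{taxon}\t{label}\t{SUBFAMILY_COLOURS[label]}")
    annotation_path = out_dir / "tree_annotation.tsv"
    annotation_path.write_text("\n".join(lines) + "\n")

    skipped_path = out_dir / "skipped_leaves.txt"
    skipped_path.write_text("".join(f"{t}\n" for t in skipped))
    return {
        "tree": tree_path,
        "annotation": annotation_path,
        "skipped_report": skipped_path,
        "skipped": skipped,
    }


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")
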