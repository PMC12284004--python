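"""Conservation of mechanism-linked residues across an anchored alignment.

Nine plectasin residues — F2, H18, K20, I22, K23, Y25, K26, Y29 and Y40 —
have been implicated in lipid II binding.  This module maps each of them
onto its alignment column (via the reference row's coordinate map) and
scores every peptide's residue at that column as *identical*,
*conservative*, *nonconservative* or *gap*.

"Conservative" is decided by a transparent residue-class scheme
(aromatic, aliphatic, positive, negative, small-polar; histidine
deliberately belongs to both aromatic and positive): two residues are
conservative substitutes when they share at least one class.  An
alternative BLOSUM62>0 mode is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .anchor_align import AnchoredAlignment, column_for_reference_position
from .io_formats import GAP, PeptideRecord
from .subfamily import SubfamilyCall

#: Plectasin, the reference CSαβ defensin (40 aa, cysteines at
#: 4, 15, 19, 30, 37, 39).
PLECTASIN_ID = "plectasin"
PLECTASIN_SEQUENCE = "GFGCNGPWDEDDMQCHNHCKSIKGYKGGYCAKGGFVCKCY"

#: The nine mechanism residues in plectasin numbering.
MECHANISM_RESIDUES: tuple[tuple[int, str], ...] = (
    (2, "F"),
    (18, "H"),
    (20, "K"),
    (22, "I"),
    (23, "K"),
    (25, "Y"),
    (26, "K"),
    (29, "Y"),
    (40, "Y"),
)

RESIDUE_CLASSES: Mapping[str, frozenset] = {
    "aromatic": frozenset("FWYH"),
    "aliphatic": frozenset("AVLIM"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "small_polar": frozenset("STNQGCP"),
}

IDENTICAL = "identical"
CONSERVATIVE = "conservative"
NONCONSERVATIVE = "nonconservative"
GAP_STATUS = "gap"
STATUSES = (IDENTICAL, CONSERVATIVE, NONCONSERVATIVE, GAP_STATUS)


def plectasin_record() -> PeptideRecord:
    return PeptideRecord(
        id=PLECTASIN_ID,
        sequence=PLECTASIN_SEQUENCE,
        description=f"{PLECTASIN_ID} reference CSαβ defensin",
        taxon_id="tax_ascomycota",
    )


@dataclass(frozen=True)
class ReferenceResidueSet:
    """Reference row id plus its mechanism residues (1-based positions)."""

    ref_id: str
    residues: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.residues]
        if positions != sorted(set(positions)):
            raise ValueError("positions must be strictly increasing")
        for _, aa in self.residues:
            if aa == GAP or len(aa) != 1:
                raise ValueError(f"bad expected residue {aa!r}")

    @classmethod
    def plectasin(cls) -> "ReferenceResidueSet":
        refset = cls(ref_id=PLECTASIN_ID, residues=MECHANISM_RESIDUES)
        for pos, aa in refset.residues:  # consistency with the sequence
            assert PLECTASIN_SEQUENCE[pos - 1] == aa
        return refset

    @classmethod
    def for_record(
        cls, record: PeptideRecord, residues: tuple[tuple[int, str], ...] = MECHANISM_RESIDUES
    ) -> "ReferenceResidueSet":
        for pos, aa in residues:
            observed = record.sequence[pos - 1] if pos <= len(record.sequence) else None
            if observed != aa:
                raise ValueError(
                    f"reference {record.id!r} has {observed!r} at {pos}, expected {aa!r}"
                )
        return cls(ref_id=record.id, residues=residues)


def conservation_status(
    expected: str, observed: str, scheme: str = "classes", matrix=None
) -> str:
    """Status of an observed residue against the expected reference one.

    ``scheme`` is ``"classes"`` (shared residue class ⇒ conservative) or
    ``"blosum62"`` (positive substitution score ⇒ conservative).  A gap
    is its own status; an observed ``X`` is nonconservative (unknown).
    """
    if observed == GAP:
        return GAP_STATUS
    if observed == expected:
        return IDENTICAL
    if observed == "X":
        return NONCONSERVATIVE
    if scheme == "classes":
        for members in RESIDUE_CLASSES.values():
            if expected in members and observed in members:
                return CONSERVATIVE
        return NONCONSERVATIVE
    if scheme == "blosum62":
        from Bio.Align import substitution_matrices

        matrix = matrix if matrix is not None else substitution_matrices.load("BLOSUM62")
        return CONSERVATIVE if matrix[expected, observed] > 0 else NONCONSERVATIVE
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class ConservationReport:
    """Long-format per-(position × peptide) statuses plus tallies."""

    long: pd.DataFrame
    per_position: pd.DataFrame

    def fraction(self, ref_position: int, status: str, subfamily: str | None = None) -> float:
        rows = self.long[self.long["ref_position"] == ref_position]
        if subfamily is not None:
            rows = rows[rows["subfamily"] == subfamily]
        if rows.empty:
            return 0.0
        return float((rows["status"] == status).mean())


def score_mechanism_residues(
    aln: AnchoredAlignment,
    refset: ReferenceResidueSet,
    calls: Iterable[SubfamilyCall] = (),
    scheme: str = "classes",
) -> ConservationReport:
    """Score every peptide at each mechanism-residue column.

    The reference row must be present in the alignment; its 1-based
    positions are mapped to columns through the alignment's coordinate
    map.  Tallies are aggregated per subfamily using the supplied calls
    (rows without a call are reported under ``"unlabelled"``).
    """
    if refset.ref_id not in aln.ids:
        raise LookupError(
            f"reference row {refset.ref_id!r} absent from the alignment"
        )
    label_of = {c.peptide_id: c.label for c in calls}
    records = []
    for pos, expected in refset.residues:
        col = column_for_reference_position(aln, refset.ref_id, pos)
        for rid, row in zip(aln.ids, aln.rows):
            observed = row[col]
            records.append(
                {
                    "peptide": rid,
                    "ref_position": pos,
                    "expected": expected,
                    "observed": observed,
                    "status": conservation_status(expected, observed, scheme=scheme),
                    "subfamily": label_of.get(rid, "unlabelled"),
                }
            )
    long = pd.DataFrame.from_records(records)
    per_position = (
        long.groupby(["ref_position", "subfamily", "status"])
        .size()
        .rename("count")
        .reset_index()
    )
    return ConservationReport(long=long, per_position=per_position)
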