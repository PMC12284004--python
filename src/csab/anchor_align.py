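"""Cysteine-anchored multiple alignment.

Family members share the six-cysteine CSαβ scaffold, so a useful multiple
alignment must keep each scaffold cysteine in its own all-cysteine anchor
column.  Rather than post-editing a general-purpose aligner's output, the
seven inter-anchor segments are aligned independently and concatenated
around single-residue anchor columns:

* the N-terminal loop is right-justified toward C1 (padding only), so the
  motif positions C1−1, C1−2, C1−3 used by subfamily classification are
  column-stable;
* the C-terminal tail is left-justified;
* the five interior loops are aligned by the center-star method with
  affine gap penalties (or merely justified, in ``pad`` mode).

The center-star merge is performed through per-star-position gap-insertion
counts, which makes the resulting block independent of the input order of
the non-star rows; star ties are broken by the lexicographically smallest
segment, so permuting the input rows never changes the anchor columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GAP
from .scaffold import MaturePeptide


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for segment alignment.

    A gap of length *k* costs ``gap_open + k * gap_extend`` in the units
    of the substitution matrix.  ``mode`` selects center-star alignment of
    the interior loops or plain justification (``pad``), the latter being
    a trivially verifiable baseline.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    mode: str = "center_star"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.mode not in ("center_star", "pad"):
            raise ValueError(f"unknown mode {self.mode!r}")


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=32)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(matrix_name)
    # Biopython charges open_gap_score for the first gap position, so a
    # length-k gap costs open + k*extend under this parameterisation.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _gap_cost(length: int, params: AlignParams) -> float:
    return 0.0 if length == 0 else params.gap_open + length * params.gap_extend


def pairwise_score(a: str, b: str, params: AlignParams) -> float:
    """Optimal global pairwise alignment score of two segments."""
    if not a and not b:
        return 0.0
    if not a or not b:
        return -_gap_cost(max(len(a), len(b)), params)
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    return float(aligner.score(a, b))


def _pairwise_alignment(star: str, seg: str, params: AlignParams) -> tuple[str, str]:
    """Deterministic optimal global alignment (gapped strings)."""
    if not seg:
        return star, GAP * len(star)
    if not star:
        return GAP * len(seg), seg
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    aln = aligner.align(star, seg)[0]
    return str(aln[0]), str(aln[1])


def sum_of_pairs_score(rows: Sequence[str], params: AlignParams) -> float:
    """Sum-of-pairs score of a gapped block with affine gap accounting.

    Each pair of rows is projected (columns where both rows have gaps are
    dropped) and scored as a global pairwise alignment: matched residues
    through the substitution matrix, each maximal gap run as
    ``open + len * extend``.
    """
    matrix = _matrix(params.matrix_name)
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            gap_run_i = gap_run_j = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP and b == GAP:
                    continue
                if a == GAP:
                    gap_run_i += 1
                    if gap_run_j:
                        total -= _gap_cost(gap_run_j, params)
                        gap_run_j = 0
                elif b == GAP:
                    gap_run_j += 1
                    if gap_run_i:
                        total -= _gap_cost(gap_run_i, params)
                        gap_run_i = 0
                else:
                    total += matrix[a, b]
                    if gap_run_i:
                        total -= _gap_cost(gap_run_i, params)
                        gap_run_i = 0
                    if gap_run_j:
                        total -= _gap_cost(gap_run_j, params)
                        gap_run_j = 0
            total -= _gap_cost(gap_run_i, params) + _gap_cost(gap_run_j, params)
    return total


def _choose_star(segments: Sequence[str], params: AlignParams) -> int:
    """Index of the star segment: maximal summed pairwise score; ties go
    to the lexicographically smallest segment (stable under permutation),
    then to the first index."""
    cache: dict[tuple[str, str], float] = {}

    def score(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = pairwise_score(key[0], key[1], params)
        return cache[key]

    best_idx = 0
    best_key: tuple[float, str] | None = None
    for i, seg in enumerate(segments):
        total = sum(score(seg, other) for j, other in enumerate(segments) if j != i)
        key = (-total, seg)
        if best_key is None or key < best_key:
            best_key = key
            best_idx = i
    return best_idx


def align_segment_center_star(
    segments: Sequence[str], params: AlignParams = AlignParams()
) -> list[str]:
    """Center-star multiple alignment of loop segments.

    Chooses the star as the segment maximising its summed pairwise score
    against all others, aligns every other segment to the star by optimal
    global pairwise alignment with affine gaps, and merges the pairwise
    alignments by taking, at each star position, the maximum number of
    inserted columns required by any row ("once a gap, always a gap";
    existing columns are never shortened).  Deterministic for a fixed
    multiset of segments.
    """
    if not segments:
        raise ValueError("need at least one segment")
    n = len(segments)
    if n == 1:
        return [segments[0]]
    if len(set(segments)) == 1:
        return list(segments)

    star_idx = _choose_star(segments, params)
    star = segments[star_idx]
    slots = len(star) + 1

    # Per-row: characters falling in each insertion slot (between star
    # residues) and the character aligned to each star residue.
    slot_chars: list[list[str]] = []
    anchor_chars: list[list[str]] = []
    insert_counts = [0] * slots
    for seg in segments:
        if seg == star:
            slot_chars.append([""] * slots)
            anchor_chars.append(list(star))
            continue
        star_g, seg_g = _pairwise_alignment(star, seg, params)
        slots_here = [""] * slots
        anchors_here: list[str] = []
        pos = 0
        for sc, gc in zip(star_g, seg_g):
            if sc == GAP:
                slots_here[pos] += gc
            else:
                anchors_here.append(gc)
                pos += 1
        slot_chars.append(slots_here)
        anchor_chars.append(anchors_here)
        for k in range(slots):
            insert_counts[k] = max(insert_counts[k], len(slots_here[k]))

    rows: list[str] = []
    for slots_here, anchors_here in zip(slot_chars, anchor_chars):
        parts: list[str] = []
        for k in range(slots):
            chunk = slots_here[k]
            parts.append(chunk + GAP * (insert_counts[k] - len(chunk)))
            if k < len(star):
                parts.append(anchors_here[k])
        rows.append("".join(parts))
    return rows


def _justify(segments: Sequence[str], right: bool) -> list[str]:
    width = max((len(s) for s in segments), default=0)
    if right:
        return [GAP * (width - len(s)) + s for s in segments]
    return [s + GAP * (width - len(s)) for s in segments]


@dataclass
class AnchoredAlignment:
    """Multiple alignment with six all-cysteine anchor columns.

    ``anchor_columns`` are 0-based internal column indices;
    ``segment_blocks`` are seven ``(start, end)`` half-open column ranges
    for N-loop, the five interior loops, and the C-tail.  Row↔column
    coordinate maps are built lazily and are mutually inverse on non-gap
    cells.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    anchor_columns: tuple[int, ...]
    segment_blocks: tuple[tuple[int, int], ...]
    _row_to_col: dict[str, tuple[int, ...]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("rows have unequal widths")
        for col in self.anchor_columns:
            bad = [rid for rid, row in zip(self.ids, self.rows) if row[col] != "C"]
            if bad:
                raise ValueError(f"anchor column {col} not all-C (rows {bad[:3]})")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)]

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def _map_for(self, row_id: str) -> tuple[int, ...]:
        if row_id not in self._row_to_col:
            self._row_to_col[row_id] = tuple(
                col for col, ch in enumerate(self.row(row_id)) if ch != GAP
            )
        return self._row_to_col[row_id]

    def column_for_position(self, row_id: str, pos: int) -> int:
        """0-based column of the ``pos``-th (1-based) residue of a row."""
        if row_id not in self.ids:
            raise LookupError(f"unknown row id {row_id!r}")
        mapping = self._map_for(row_id)
        if not 1 <= pos <= len(mapping):
            raise LookupError(
                f"position {pos} outside 1..{len(mapping)} for row {row_id!r}"
            )
        return mapping[pos - 1]

    def position_for_column(self, row_id: str, col: int) -> Optional[int]:
        """1-based residue position at a column, or None on a gap."""
        row = self.row(row_id)
        if not 0 <= col < len(row):
            raise LookupError(f"column {col} outside 0..{len(row) - 1}")
        if row[col] == GAP:
            return None
        return col - row[:col].count(GAP) + 1


def column_for_reference_position(
    aln: AnchoredAlignment, ref_id: str, ref_pos: int
) -> int:
    """Column (0-based) holding the reference row's 1-based residue."""
    return aln.column_for_position(ref_id, ref_pos)


def build_anchored_alignment(
    peptides: Sequence[MaturePeptide], params: AlignParams = AlignParams()
) -> AnchoredAlignment:
    """Align mature peptides with the six cysteines as anchor columns.

    The seven scaffold segments are aligned block-by-block (N-loop
    right-justified, C-tail left-justified, interior loops center-star or
    padded per ``params.mode``) and concatenated with single-residue
    anchor columns in between.
    """
    if not peptides:
        raise ValueError("need at least one peptide")
    ids = tuple(p.id for p in peptides)

    blocks: list[list[str]] = []
    for seg_idx in range(7):
        segments = [p.scaffold.segments[seg_idx] for p in peptides]
        if seg_idx == 0:
            blocks.append(_justify(segments, right=True))
        elif seg_idx == 6 or params.mode == "pad":
            blocks.append(_justify(segments, right=False))
        else:
            gapped = align_segment_center_star(segments, params)
            blocks.append(gapped)

    anchor_columns: list[int] = []
    segment_blocks: list[tuple[int, int]] = []
    col = 0
    for seg_idx in range(7):
        width = len(blocks[seg_idx][0]) if blocks[seg_idx] else 0
        segment_blocks.append((col, col + width))
        col += width
        if seg_idx < 6:
            anchor_columns.append(col)
            col += 1

    rows = []
    for row_idx in range(len(peptides)):
        parts = []
        for seg_idx in range(7):
            parts.append(blocks[seg_idx][row_idx])
            if seg_idx < 6:
                parts.append("C")
        rows.append("".join(parts))

    return AnchoredAlignment(
        ids=ids,
        rows=tuple(rows),
        anchor_columns=tuple(anchor_columns),
        segment_blocks=tuple(segment_blocks),
    )
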