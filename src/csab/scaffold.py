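"""Detection of the three-disulphide CSαβ six-cysteine scaffold.

The CSαβ fold is held together by three disulphide bonds between six
cysteines (C1…C6).  Consecutive cysteines sit at characteristic spacings:
the default windows below generalise the plectasin anchor spacing
(cysteines at 4, 15, 19, 30, 37, 39) with slack for the 34–60-residue
length range observed across the family.  Detection is an exhaustive,
window-constrained search over cysteine subsets with deterministic
tie-breaking, so the same sequence always yields the same scaffold.

Maturation (`trim_to_mature`) is scaffold-anchored: instead of a learned
leader-peptide model, the mature region is taken as a bounded window
around the detected scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .io_formats import PeptideRecord


@dataclass(frozen=True)
class ScaffoldConfig:
    """Spacing constraints for the six-cysteine scaffold search.

    ``loop_windows`` holds (min, max) counts of residues *between*
    consecutive cysteines for the five inter-cysteine loops C1–C2 … C5–C6.
    ``max_nloop`` bounds the N-terminal loop (residues before C1)
    considered during search; ``mature_length_bounds`` bounds the length
    of an acceptable mature peptide.
    """

    loop_windows: tuple[tuple[int, int], ...] = (
        (4, 16),  # C1-C2
        (2, 6),   # C2-C3
        (6, 14),  # C3-C4
        (3, 10),  # C4-C5
        (1, 3),   # C5-C6
    )
    max_nloop: int = 25
    mature_length_bounds: tuple[int, int] = (20, 80)

    def __post_init__(self) -> None:
        if len(self.loop_windows) != 5:
            raise ValueError("exactly five inter-cysteine windows required")
        for lo, hi in self.loop_windows:
            if lo < 0 or lo > hi:
                raise ValueError(f"bad spacing window ({lo}, {hi})")
        if self.max_nloop < 0:
            raise ValueError("max_nloop must be >= 0")
        lo, hi = self.mature_length_bounds
        if lo < 6 or lo > hi:
            raise ValueError(f"bad mature length bounds ({lo}, {hi})")

    @property
    def window_midpoints(self) -> tuple[float, ...]:
        return tuple((lo + hi) / 2 for lo, hi in self.loop_windows)


DEFAULT_SCAFFOLD_CONFIG = ScaffoldConfig()


@dataclass(frozen=True)
class CysScaffold:
    """Six anchor cysteine positions and the seven segments they delimit.

    ``cys_positions`` are 1-based and strictly increasing; ``segments`` are
    the N-loop (before C1), the five inter-cysteine loops, and the C-tail
    (after C6).  Joining the segments with ``C`` at each anchor
    reconstructs the source sequence exactly.
    """

    cys_positions: tuple[int, ...]
    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.cys_positions) != 6 or len(self.segments) != 7:
            raise ValueError("scaffold needs 6 cysteines and 7 segments")
        if list(self.cys_positions) != sorted(set(self.cys_positions)):
            raise ValueError("cysteine positions must be strictly increasing")

    @classmethod
    def from_positions(cls, sequence: str, positions: tuple[int, ...]) -> "CysScaffold":
        for pos in positions:
            if sequence[pos - 1] != "C":
                raise ValueError(f"position {pos} is {sequence[pos - 1]!r}, not C")
        cuts = [0] + [p for p in positions] + [len(sequence) + 1]
        segments = tuple(
            sequence[cuts[i] : cuts[i + 1] - 1] for i in range(6)
        ) + (sequence[positions[-1] :],)
        return cls(cys_positions=tuple(positions), segments=segments)

    def reconstruct(self) -> str:
        out = self.segments[0]
        for seg in self.segments[1:]:
            out += "C" + seg
        return out

    @property
    def nloop(self) -> str:
        return self.segments[0]

    @property
    def tail(self) -> str:
        return self.segments[6]

    @property
    def loop_gaps(self) -> tuple[int, ...]:
        """Residue counts between consecutive cysteines."""
        p = self.cys_positions
        return tuple(p[i + 1] - p[i] - 1 for i in range(5))

    def shifted(self, offset: int) -> "CysScaffold":
        return replace(
            self, cys_positions=tuple(p + offset for p in self.cys_positions)
        )


@dataclass(frozen=True)
class MaturePeptide:
    """A mature CSαβ peptide: source record, scaffold, and trim coordinates.

    ``mature_start``/``mature_end`` are 1-based inclusive coordinates in
    the source sequence; the scaffold's cysteine positions refer to the
    mature sequence.
    """

    record: PeptideRecord
    scaffold: CysScaffold
    mature_start: int
    mature_end: int

    @property
    def sequence(self) -> str:
        return self.record.sequence[self.mature_start - 1 : self.mature_end]

    def __len__(self) -> int:
        return self.mature_end - self.mature_start + 1

    @property
    def id(self) -> str:
        return self.record.id

    def residue(self, pos: int) -> Optional[str]:
        """1-based lookup in the mature sequence; None outside bounds."""
        if 1 <= pos <= len(self):
            return self.sequence[pos - 1]
        return None


def _score_key(
    gaps: tuple[int, ...], positions: tuple[int, ...], config: ScaffoldConfig
) -> tuple[int, float, tuple[int, ...]]:
    mids = config.window_midpoints
    hits = sum(1 for g, m in zip(gaps, mids) if abs(g - m) < 1.0)
    deviation = sum(abs(g - m) for g, m in zip(gaps, mids))
    # Sort key: maximise mode hits, then minimise deviation, then smallest
    # positions lexicographically (puts C1 as early as possible).
    return (-hits, deviation, positions)


def find_scaffold(
    sequence: str, config: ScaffoldConfig = DEFAULT_SCAFFOLD_CONFIG
) -> Optional[CysScaffold]:
    """Find the best six-cysteine CSαβ scaffold in ``sequence``.

    Searches cysteine subsets by depth-first extension, pruning any
    partial subset whose latest inter-cysteine gap falls outside the
    configured spacing window.  Among valid subsets the winner maximises
    the number of gaps at (within one residue of) their window midpoint,
    then minimises total deviation from the midpoints, then takes the
    smallest cysteine positions.  Returns ``None`` when no subset
    satisfies all five windows — the sequence is not a CSαβ candidate.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    cys = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
    if len(cys) < 6:
        return None

    best: tuple | None = None
    best_positions: tuple[int, ...] | None = None

    def extend(chosen: list[int], next_idx: int) -> None:
        nonlocal best, best_positions
        depth = len(chosen)
        if depth == 6:
            positions = tuple(chosen)
            gaps = tuple(positions[i + 1] - positions[i] - 1 for i in range(5))
            key = _score_key(gaps, positions, config)
            if best is None or key < best:
                best = key
                best_positions = positions
            return
        lo, hi = config.loop_windows[depth - 1]
        for idx in range(next_idx, len(cys)):
            gap = cys[idx] - chosen[-1] - 1
            if gap < lo:
                continue
            if gap > hi:
                break  # cys positions increase, so later gaps only grow
            chosen.append(cys[idx])
            extend(chosen, idx + 1)
            chosen.pop()

    for start, pos in enumerate(cys):
        if pos - 1 > config.max_nloop:
            break
        extend([pos], start + 1)

    if best_positions is None:
        return None
    return CysScaffold.from_positions(sequence, best_positions)


def trim_to_mature(
    record: PeptideRecord,
    config: ScaffoldConfig = DEFAULT_SCAFFOLD_CONFIG,
    max_nloop: int = 12,
    max_tail: int = 6,
) -> Optional[MaturePeptide]:
    """Trim a precursor to its mature peptide, anchored on the scaffold.

    The mature region spans from ``max(1, C1 - max_nloop)`` to
    ``min(len, C6 + max_tail)`` in the source sequence; scaffold positions
    are re-expressed relative to the mature start.  Returns ``None`` when
    no scaffold is found or the trimmed length falls outside the
    configured mature-length bounds.
    """
    # The leader may push C1 beyond max_nloop, so search with a relaxed
    # N-loop bound and let the trim window impose the final one.
    search_config = replace(
        config, max_nloop=max(config.max_nloop, len(record.sequence))
    )
    scaffold = find_scaffold(record.sequence, search_config)
    if scaffold is None:
        return None
    c1, c6 = scaffold.cys_positions[0], scaffold.cys_positions[5]
    mature_start = max(1, c1 - max_nloop)
    mature_end = min(len(record.sequence), c6 + max_tail)
    length = mature_end - mature_start + 1
    lo, hi = config.mature_length_bounds
    if not lo <= length <= hi:
        return None
    mature_seq = record.sequence[mature_start - 1 : mature_end]
    shifted = scaffold.shifted(-(mature_start - 1))
    return MaturePeptide(
        record=record,
        scaffold=CysScaffold.from_positions(mature_seq, shifted.cys_positions),
        mature_start=mature_start,
        mature_end=mature_end,
    )


def as_mature(
    record: PeptideRecord,
    config: ScaffoldConfig = DEFAULT_SCAFFOLD_CONFIG,
    max_nloop: int = 12,
    max_tail: int = 6,
) -> Optional[MaturePeptide]:
    """Convenience: trim a record assumed close to mature already."""
    return trim_to_mature(record, config, max_nloop=max_nloop, max_tail=max_tail)
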