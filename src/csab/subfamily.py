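"""Rule-based GXGCP / XTCD subfamily classification.

Mature CSαβ peptides split into two structural subfamilies around the
first scaffold cysteine (C1):

* **GXGCP** — short N-terminal loop ending Gly–aromatic–Gly immediately
  before C1, usually with Pro at C1+1 (actifensin: Gly1-Phe2-Gly3-Cys4-Pro5).
  Trans-kingdom: bacteria plus ancient invertebrates and fungi.
* **XTCD** — extended N-terminal loop ending Thr at C1−1 with Asp at
  C1+1, typically followed by an aliphatic pair (e.g. Leu-Leu).
  Eukaryote-only, concentrated in recent insect orders.

Because only a subset of either group carries its full motif, the label
is decided by a 2-of-3 evidence vote in which N-loop length is one vote —
loop length is the single feature that separates the groups across the
whole family.  The conserved histidine preceding C3 is reported as
evidence but never used for labelling: it is shared by both subfamilies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .scaffold import MaturePeptide

AROMATIC = frozenset("FWYH")
ALIPHATIC = frozenset("AVLIM")

GXGCP = "GXGCP"
XTCD = "XTCD"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClassifierConfig:
    """Residue sets, loop-length thresholds and evidence toggles."""

    aromatic: frozenset = AROMATIC
    aliphatic: frozenset = ALIPHATIC
    short_nloop_max: int = 5
    long_nloop_min: int = 6
    aliphatic_offsets: tuple[int, int] = (2, 3)  # offsets after C1
    use_nloop: bool = True
    use_gxg: bool = True
    use_pro: bool = True
    use_xtcd_motif: bool = True
    use_aliphatic_pair: bool = True
    min_score: int = 2

    def __post_init__(self) -> None:
        if self.short_nloop_max >= self.long_nloop_min:
            raise ValueError("short_nloop_max must be < long_nloop_min")


DEFAULT_CLASSIFIER_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class SubfamilyCall:
    """Per-peptide subfamily label with its motif evidence."""

    peptide_id: str
    label: str
    nloop_len: int
    has_gxg: bool
    aromatic_x: Optional[str]
    has_pro_at_c1plus1: bool
    has_xtcd: bool
    has_aliphatic_pair: bool
    has_prec3_his: bool
    has_double_ala_helix: bool
    score_gxgcp: int
    score_xtcd: int
    length: int
    taxon_id: Optional[str] = None


def check_preC3_his(peptide: MaturePeptide) -> bool:
    """True iff the residue immediately preceding C3 is histidine.

    This single conserved histidine sits inside the α-helix in both
    subfamilies (plectasin H18 before C19; actifensin His17)."""
    c3 = peptide.scaffold.cys_positions[2]
    return peptide.residue(c3 - 1) == "H"


def classify(
    peptide: MaturePeptide, config: ClassifierConfig = DEFAULT_CLASSIFIER_CONFIG
) -> SubfamilyCall:
    """Classify one mature peptide as GXGCP, XTCD, or UNCLASSIFIED.

    Evidence is read at fixed offsets from C1; each subfamily's score is
    the number of its satisfied components (loop length, motif, C1+1
    residue / aliphatic pair).  The label is the unique maximiser when
    its score reaches ``min_score``, otherwise UNCLASSIFIED.
    """
    c1 = peptide.scaffold.cys_positions[0]
    nloop_len = c1 - 1
    res = peptide.residue

    trio = (res(c1 - 3), res(c1 - 2), res(c1 - 1))
    has_gxg = (
        trio[0] == "G"
        and trio[1] is not None
        and trio[1] in config.aromatic
        and trio[2] == "G"
    )
    aromatic_x = trio[1] if has_gxg else None
    has_pro = res(c1 + 1) == "P"
    has_xtcd = res(c1 - 1) == "T" and res(c1 + 1) == "D"
    o1, o2 = config.aliphatic_offsets
    pair = (res(c1 + o1), res(c1 + o2))
    has_aliphatic_pair = all(r is not None and r in config.aliphatic for r in pair)

    loop23 = peptide.scaffold.segments[2]
    has_double_ala = "AA" in loop23

    score_gxgcp = (
        int(config.use_nloop and nloop_len <= config.short_nloop_max)
        + int(config.use_gxg and has_gxg)
        + int(config.use_pro and has_pro)
    )
    score_xtcd = (
        int(config.use_nloop and nloop_len >= config.long_nloop_min)
        + int(config.use_xtcd_motif and has_xtcd)
        + int(config.use_aliphatic_pair and has_aliphatic_pair)
    )

    if score_gxgcp > score_xtcd and score_gxgcp >= config.min_score:
        label = GXGCP
    elif score_xtcd > score_gxgcp and score_xtcd >= config.min_score:
        label = XTCD
    else:
        label = UNCLASSIFIED

    return SubfamilyCall(
        peptide_id=peptide.id,
        label=label,
        nloop_len=nloop_len,
        has_gxg=has_gxg,
        aromatic_x=aromatic_x,
        has_pro_at_c1plus1=has_pro,
        has_xtcd=has_xtcd,
        has_aliphatic_pair=has_aliphatic_pair,
        has_prec3_his=check_preC3_his(peptide),
        has_double_ala_helix=has_double_ala,
        score_gxgcp=score_gxgcp,
        score_xtcd=score_xtcd,
        length=len(peptide),
        taxon_id=peptide.record.taxon_id,
    )


def summarize_calls(calls: Iterable[SubfamilyCall]) -> dict:
    """Counts, percentages and peptide-length statistics per label."""
    calls = list(calls)
    n = len(calls)
    counts = Counter(c.label for c in calls)
    summary: dict = {
        "n": n,
        "counts": {label: counts.get(label, 0) for label in (GXGCP, XTCD, UNCLASSIFIED)},
        "fractions_pct": {},
        "length": {},
        "prec3_his": {},
    }
    for label in (GXGCP, XTCD, UNCLASSIFIED):
        summary["fractions_pct"][label] = (
            round(100.0 * counts.get(label, 0) / n, 1) if n else 0.0
        )
    if n:
        lengths = [c.length for c in calls]
        summary["length"] = {
            "min": min(lengths),
            "max": max(lengths),
            "mean": round(sum(lengths) / n, 2),
        }
    his_total = sum(c.has_prec3_his for c in calls)
    summary["prec3_his"]["overall"] = {"count": his_total, "of": n}
    for label in (GXGCP, XTCD):
        members = [c for c in calls if c.label == label]
        summary["prec3_his"][label] = {
            "count": sum(c.has_prec3_his for c in members),
            "of": len(members),
        }
    return summary
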