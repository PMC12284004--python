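"""Synthetic CSαβ peptide corpora with planted, recorded ground truth.

Emulates the real study corpus — reviewed arthropod-defensin family
members plus HMM-identified bacterial actifensins — as a generator of
34–60-residue six-cysteine peptides: a GXGCP-like or XTCD-like
N-terminus planted at configurable fidelities, the conserved pre-C3
histidine, mechanism-residue columns filled from plectasin-expected
residues, and taxon labels spanning bacteria and invertebrate phyla.
Default fidelities follow the family's observed motif frequencies
(GXG 52/88 ≈ 0.59, Pro5 80/88 ≈ 0.91, His 72/88 ≈ 0.82, XTCD motif
33/33, aliphatic pair 23/33 ≈ 0.70); the default mixture is 88 GXGCP to
35 XTCD and lengths are sampled to range 34–60 with mean ≈ 38.

Every generated mature peptide carries exactly six cysteines placed
inside the default scaffold spacing windows, so scaffold detection is a
closure property of the corpus.  Leaders in precursor mode are
cysteine-free (a documented simplification — real leaders may contain
cysteine) and the background alphabet excludes cysteine for the same
reason.  A fixed seed makes the output byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io_formats import LineageTable, PeptideRecord
from .subfamily import ALIPHATIC, AROMATIC, GXGCP, XTCD

#: Background alphabet: canonical residues minus cysteine.
BACKGROUND = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY") - {"C"}))

#: Synthetic clades shaped like the family's real spread: GXGCP taxa span
#: bacteria plus ancient invertebrates and fungi; XTCD taxa are recent
#: insect orders.  Names are synthetic stand-ins, not real taxids.
GXGCP_TAXA: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("tax_actinomycetales", ("Root", "Bacteria", "Actinomycetota", "Actinomycetales"), "Actinomyces-like"),
    ("tax_bacillales", ("Root", "Bacteria", "Bacillota", "Bacillales"), "Bacillus-like"),
    ("tax_ascomycota", ("Root", "Eukaryota", "Fungi", "Ascomycota"), "Ascomycete fungus"),
    ("tax_mollusca", ("Root", "Eukaryota", "Mollusca", "Mytilida"), "Mussel"),
    ("tax_odonata", ("Root", "Eukaryota", "Arthropoda", "Odonata"), "Dragonfly"),
    ("tax_scorpiones", ("Root", "Eukaryota", "Arthropoda", "Scorpiones"), "Scorpion"),
)
XTCD_TAXA: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("tax_coleoptera", ("Root", "Eukaryota", "Arthropoda", "Coleoptera"), "Beetle"),
    ("tax_diptera", ("Root", "Eukaryota", "Arthropoda", "Diptera"), "Fly"),
    ("tax_hemiptera", ("Root", "Eukaryota", "Arthropoda", "Hemiptera"), "True bug"),
    ("tax_hymenoptera", ("Root", "Eukaryota", "Arthropoda", "Hymenoptera"), "Wasp"),
    ("tax_lepidoptera", ("Root", "Eukaryota", "Arthropoda", "Lepidoptera"), "Moth"),
)

#: Mechanism-residue planting slots, keyed by plectasin position:
#: (anchor index 0-based, offset from that anchor, expected residue).
#: H18 (= C3−1) is governed by ``p_his`` rather than listed here.
MECH_SLOTS: Mapping[int, tuple[int, int, str]] = {
    20: (2, 1, "K"),
    22: (2, 3, "I"),
    23: (2, 4, "K"),
    25: (2, 6, "Y"),
    26: (2, 7, "K"),
    29: (3, -1, "Y"),
    40: (5, 1, "Y"),
}

#: Residue classes used for conservative-miss draws.
_CLASS_OF = {
    **{aa: frozenset(AROMATIC) for aa in AROMATIC},
    **{aa: frozenset(ALIPHATIC) for aa in ALIPHATIC},
    "K": frozenset("KR"),
    "R": frozenset("KR"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    Counts, length bounds, motif fidelities and the loop-length sampling
    ranges below define what a "realistic corpus" means to the rest of
    the package; all probabilities are per-peptide Bernoulli draws.
    ``mech_fidelity`` maps plectasin positions to the probability of
    planting the exact expected residue; a miss draws a same-class
    substitute, except positions listed in ``mech_background_on_miss``
    (K23, the family's known non-conserved site) which draw from the
    background.
    """

    n_gxgcp: int = 88
    n_xtcd: int = 35
    length_bounds: tuple[int, int] = (34, 60)
    target_mean_length: int = 38
    p_gxg: float = 0.59
    p_pro: float = 0.91
    p_his: float = 0.82
    p_xtcd_motif: float = 1.0
    p_aliphatic_pair: float = 0.70
    p_double_ala: float = 0.60
    mech_fidelity: Mapping[int, float] = field(
        default_factory=lambda: {20: 0.9, 22: 0.9, 23: 0.2, 25: 0.9, 26: 0.9, 29: 0.9, 40: 0.9}
    )
    mech_background_on_miss: tuple[int, ...] = (23,)
    #: In XTCD rows these positions are planted with the subfamily's own
    #: residue (Y25→R, Y40→K) at ``xtcd_mech_p``.
    xtcd_mech_overrides: Mapping[int, str] = field(
        default_factory=lambda: {25: "R", 40: "K"}
    )
    xtcd_mech_p: float = 0.8
    background_mutation_rate: float = 0.0
    # Loop-length sampling ranges (inclusive) per scaffold segment.
    nloop_gxgcp_range: tuple[int, int] = (3, 5)
    nloop_xtcd_range: tuple[int, int] = (6, 8)
    loop_ranges: tuple[tuple[int, int], ...] = (
        (5, 10),  # C1-C2
        (2, 4),   # C2-C3
        (8, 11),  # C3-C4
        (3, 7),   # C4-C5
        (1, 2),   # C5-C6
    )
    tail_range: tuple[int, int] = (1, 2)
    leader_length_range: tuple[int, int] = (15, 30)
    seed: int = 0
    max_resample: int = 1000

    def __post_init__(self) -> None:
        for name in ("p_gxg", "p_pro", "p_his", "p_xtcd_motif", "p_aliphatic_pair",
                     "p_double_ala", "xtcd_mech_p", "background_mutation_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for p in self.mech_fidelity.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("mech_fidelity entries must lie in [0, 1]")
        if self.n_gxgcp < 0 or self.n_xtcd < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.length_bounds
        if lo > hi:
            raise ValueError("length bounds out of order")
        min_total = (
            min(self.nloop_gxgcp_range[0], self.nloop_xtcd_range[0])
            + 6
            + sum(r[0] for r in self.loop_ranges)
            + self.tail_range[0]
        )
        max_total = (
            max(self.nloop_gxgcp_range[1], self.nloop_xtcd_range[1])
            + 6
            + sum(r[1] for r in self.loop_ranges)
            + self.tail_range[1]
        )
        if max_total < lo or min_total > hi:
            raise ValueError(
                f"infeasible config: achievable lengths {min_total}-{max_total} "
                f"never intersect bounds {lo}-{hi}"
            )


def _rand_int(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _background(rng: np.random.Generator, n: int) -> list[str]:
    return [BACKGROUND[i] for i in rng.integers(0, len(BACKGROUND), size=n)]


def _draw_excluding(rng: np.random.Generator, exclude: frozenset) -> str:
    choices = [aa for aa in BACKGROUND if aa not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


def _conservative_substitute(rng: np.random.Generator, expected: str) -> str:
    members = sorted(_CLASS_OF.get(expected, frozenset({expected})) - {expected, "C"})
    if not members:
        return expected
    return members[int(rng.integers(0, len(members)))]


def _sample_segment_lengths(
    rng: np.random.Generator, config: GeneratorConfig, subfamily: str
) -> tuple[int, list[int], int]:
    nloop_range = (
        config.nloop_gxgcp_range if subfamily == GXGCP else config.nloop_xtcd_range
    )
    lo, hi = config.length_bounds
    for _ in range(config.max_resample):
        nloop = _rand_int(rng, nloop_range)
        gaps = [_rand_int(rng, r) for r in config.loop_ranges]
        tail = _rand_int(rng, config.tail_range)
        total = nloop + 6 + sum(gaps) + tail
        if lo <= total <= hi:
            return nloop, gaps, tail
    raise ValueError("could not sample a peptide length inside the bounds")


def _build_peptide(
    rng: np.random.Generator, config: GeneratorConfig, subfamily: str
) -> tuple[str, dict]:
    """One mature peptide plus its planted-feature truth row."""
    nloop_len, gaps, tail_len = _sample_segment_lengths(rng, config, subfamily)
    segments = [_background(rng, nloop_len)] + [
        _background(rng, g) for g in gaps
    ] + [_background(rng, tail_len)]
    # Extra background churn happens before planting so planted features
    # stay exact at their configured fidelities.
    if config.background_mutation_rate > 0:
        for seg in segments:
            for i in range(len(seg)):
                if rng.random() < config.background_mutation_rate:
                    seg[i] = _background(rng, 1)[0]
    truth: dict = {
        "subfamily": subfamily,
        "nloop_len": nloop_len,
        "gaps": tuple(gaps),
        "tail_len": tail_len,
    }

    # Conserved pre-C3 histidine (plectasin H18); both subfamilies.
    plant_his = bool(rng.random() < config.p_his)
    loop23 = segments[2]
    loop23[-1] = "H" if plant_his else _draw_excluding(rng, frozenset("H"))
    truth["his"] = plant_his

    # Mechanism residues at plectasin-homologous scaffold offsets.
    seg_of_anchor = {2: segments[3], 3: segments[3], 5: segments[6]}
    for pos, (anchor, offset, expected) in MECH_SLOTS.items():
        seg = seg_of_anchor[anchor]
        idx = offset - 1 if anchor in (2, 5) else len(seg) + offset
        if not 0 <= idx < len(seg):
            truth[f"mech_{pos}"] = ""
            continue
        if subfamily == XTCD and pos in config.xtcd_mech_overrides:
            planted = (
                config.xtcd_mech_overrides[pos]
                if rng.random() < config.xtcd_mech_p
                else _conservative_substitute(rng, expected)
            )
        else:
            fidelity = config.mech_fidelity.get(pos, 1.0)
            if rng.random() < fidelity:
                planted = expected
            elif pos in config.mech_background_on_miss:
                planted = _draw_excluding(rng, frozenset(expected))
            else:
                planted = _conservative_substitute(rng, expected)
        seg[idx] = planted
        truth[f"mech_{pos}"] = planted

    # N-terminal motif block around C1.
    nloop = segments[0]
    loop12 = segments[1]
    if subfamily == GXGCP:
        plant_gxg = bool(rng.random() < config.p_gxg)
        if plant_gxg:
            aromatic = sorted(AROMATIC)[int(rng.integers(0, len(AROMATIC)))]
            nloop[-3:] = ["G", aromatic, "G"]
            truth["aromatic_x"] = aromatic
        else:
            nloop[-1] = _draw_excluding(rng, frozenset("GT"))
            truth["aromatic_x"] = ""
        plant_pro = bool(rng.random() < config.p_pro)
        loop12[0] = "P" if plant_pro else _draw_excluding(rng, frozenset("PD"))
        truth.update(gxg=plant_gxg, pro=plant_pro, xtcd_motif=False, aliphatic_pair=False,
                     double_ala=False)
    else:
        plant_motif = bool(rng.random() < config.p_xtcd_motif)
        if plant_motif:
            nloop[-1] = "T"
            loop12[0] = "D"
        else:
            nloop[-1] = _draw_excluding(rng, frozenset("TG"))
            loop12[0] = _draw_excluding(rng, frozenset("DP"))
        # The N-loop must not look GXGCP-like by accident.
        if len(nloop) >= 2 and nloop[-2] in AROMATIC:
            nloop[-2] = _draw_excluding(rng, AROMATIC)
        plant_pair = bool(rng.random() < config.p_aliphatic_pair)
        if plant_pair:
            aliphatic = sorted(ALIPHATIC)
            loop12[1] = aliphatic[int(rng.integers(0, len(aliphatic)))]
            loop12[2] = aliphatic[int(rng.integers(0, len(aliphatic)))]
        else:
            loop12[1] = _draw_excluding(rng, ALIPHATIC)
        plant_ala = bool(rng.random() < config.p_double_ala) and len(loop23) >= 3
        if plant_ala:
            loop23[0:2] = ["A", "A"]
        truth.update(gxg=False, pro=False, aromatic_x="", xtcd_motif=plant_motif,
                     aliphatic_pair=plant_pair, double_ala=plant_ala)

    parts = ["".join(segments[0])]
    for seg in segments[1:]:
        parts.append("C")
        parts.append("".join(seg))
    sequence = "".join(parts)
    truth["length"] = len(sequence)
    return sequence, truth


def _sample_taxon(
    rng: np.random.Generator, subfamily: str
) -> tuple[str, tuple[str, ...]]:
    pool = GXGCP_TAXA if subfamily == GXGCP else XTCD_TAXA
    taxon_id, lineage, _ = pool[int(rng.integers(0, len(pool)))]
    return taxon_id, lineage


def generate_corpus(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[PeptideRecord], pd.DataFrame]:
    """Generate mature peptides plus a truth table of planted features.

    The truth table has one row per peptide: subfamily, taxon, segment
    lengths, and every planted feature (motifs, pre-C3 His, mechanism
    residues) so tests can compare detected against planted."""
    rng = np.random.default_rng(config.seed)
    records: list[PeptideRecord] = []
    truth_rows: list[dict] = []
    for subfamily, count, prefix in (
        (GXGCP, config.n_gxgcp, "gx"),
        (XTCD, config.n_xtcd, "xt"),
    ):
        for i in range(count):
            sequence, truth = _build_peptide(rng, config, subfamily)
            taxon_id, lineage = _sample_taxon(rng, subfamily)
            rec_id = f"{prefix}{i + 1:04d}"
            records.append(
                PeptideRecord(
                    id=rec_id,
                    sequence=sequence,
                    description=f"{rec_id} synthetic {subfamily} peptide taxon={taxon_id}",
                    taxon_id=taxon_id,
                    lineage=lineage,
                )
            )
            truth.update(id=rec_id, taxon_id=taxon_id, mature_start=1)
            truth_rows.append(truth)
    truth = pd.DataFrame.from_records(truth_rows)
    return records, truth


def generate_precursors(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[PeptideRecord], pd.DataFrame]:
    """Mature corpus with cysteine-free leaders prepended.

    The truth table's ``mature_start`` records where the mature peptide
    really begins (1-based), for checking scaffold-anchored trimming."""
    records, truth = generate_corpus(config)
    rng = np.random.default_rng(config.seed + 1)
    out: list[PeptideRecord] = []
    starts: list[int] = []
    for rec in records:
        leader_len = _rand_int(rng, config.leader_length_range)
        leader = "".join(_background(rng, leader_len))
        out.append(
            PeptideRecord(
                id=rec.id,
                sequence=leader + rec.sequence,
                description=rec.description + " precursor",
                taxon_id=rec.taxon_id,
                lineage=rec.lineage,
            )
        )
        starts.append(leader_len + 1)
    truth = truth.copy()
    truth["mature_start"] = starts
    return out, truth


def synthetic_lineage_table() -> LineageTable:
    rows = {
        taxon_id: (lineage, name)
        for taxon_id, lineage, name in GXGCP_TAXA + XTCD_TAXA
    }
    return LineageTable(rows=rows)


def write_lineage_tsv(path) -> None:
    lines = ["taxon_id\tlineage\tname"]
    for taxon_id, lineage, name in GXGCP_TAXA + XTCD_TAXA:
        lines.append(f"{taxon_id}\t{';'.join(lineage)}\t{name}")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def synthetic_taxonomy_newick() -> str:
    """Newick tree over the synthetic clades, leaves named by taxon_id."""
    tree: dict = {}
    for taxon_id, lineage, _ in GXGCP_TAXA + XTCD_TAXA:
        node = tree
        for clade in lineage:
            node = node.setdefault(clade, {})
        node[taxon_id] = None

    def render(name: str, node: Optional[dict]) -> str:
        if not node:
            return name
        children = ",".join(render(k, v) for k, v in sorted(node.items()))
        return f"({children}){name}"

    root_name, root_node = next(iter(tree.items()))
    return render(root_name, root_node) + ";"
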