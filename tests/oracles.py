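"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration, sharing
no code path with the package's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

from csab.anchor_align import AlignParams, sum_of_pairs_score
from csab.scaffold import ScaffoldConfig

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")


def brute_force_scaffold(sequence: str, config: ScaffoldConfig):
    """Best six-cysteine subset by exhaustive enumeration.

    Checks every 6-subset of cysteine positions against the spacing
    windows and ranks valid ones by (mode hits desc, total midpoint
    deviation asc, positions asc) — the same documented criterion, but
    evaluated by a completely naive path.
    """
    cys = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
    mids = [(lo + hi) / 2 for lo, hi in config.loop_windows]
    best_key, best = None, None
    for subset in itertools.combinations(cys, 6):
        if subset[0] - 1 > config.max_nloop:
            continue
        gaps = [subset[i + 1] - subset[i] - 1 for i in range(5)]
        if any(
            not lo <= g <= hi for g, (lo, hi) in zip(gaps, config.loop_windows)
        ):
            continue
        hits = sum(1 for g, m in zip(gaps, mids) if abs(g - m) < 1.0)
        deviation = sum(abs(g - m) for g, m in zip(gaps, mids))
        key = (-hits, deviation, subset)
        if best_key is None or key < best_key:
            best_key, best = key, subset
    return best


def brute_force_msa_optimum(segments: list[str], params: AlignParams) -> float:
    """Optimal sum-of-pairs score over all gap placements up to width
    max_len + 2 (tiny instances only)."""
    max_len = max(len(s) for s in segments)
    best = None
    for width in range(max_len, max_len + 3):
        placements = []
        for s in segments:
            opts = []
            for cols in itertools.combinations(range(width), len(s)):
                row = ["-"] * width
                for c, ch in zip(cols, s):
                    row[c] = ch
                opts.append("".join(row))
            placements.append(opts)
        n = len(segments)
        shape = [len(p) for p in placements]
        total = np.zeros(shape)
        for i in range(n):
            for j in range(i + 1, n):
                table = np.empty((shape[i], shape[j]))
                for a, row_a in enumerate(placements[i]):
                    for b, row_b in enumerate(placements[j]):
                        table[a, b] = sum_of_pairs_score([row_a, row_b], params)
                idx = [np.newaxis] * n
                idx[i] = slice(None)
                idx[j] = slice(None)
                total = total + table[tuple(idx)]
        m = float(total.max())
        best = m if best is None else max(best, m)
    return best


def random_protein(rng: np.random.Generator, length: int, p_cys: float = 0.12) -> str:
    """Random sequence with tunable cysteine density."""
    others = [aa for aa in AMINO_ACIDS if aa != "C"]
    return "".join(
        "C" if rng.random() < p_cys else others[int(rng.integers(0, len(others)))]
        for _ in range(length)
    )


def homologous_segments(rng: np.random.Generator) -> list[str]:
    """A small set of related loop segments: a common base with point
    substitutions and occasional single-residue indels — the kind of
    input the segment aligner sees inside one scaffold block."""
    n = int(rng.integers(2, 5))
    base_len = int(rng.integers(1, 5))
    base = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=base_len)]
    out = []
    for _ in range(n):
        seg = [
            aa if rng.random() >= 0.2 else AMINO_ACIDS[int(rng.integers(0, 20))]
            for aa in base
        ]
        roll = rng.random()
        if roll < 0.15 and len(seg) > 1:
            seg.pop(int(rng.integers(0, len(seg))))
        elif roll < 0.30 and len(seg) < 4:
            seg.insert(
                int(rng.integers(0, len(seg) + 1)),
                AMINO_ACIDS[int(rng.integers(0, 20))],
            )
        out.append("".join(seg))
    return out
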