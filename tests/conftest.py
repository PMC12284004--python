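from __future__ import annotations

import pytest

from csab.conservation import plectasin_record
from csab.io_formats import PeptideRecord
from csab.scaffold import CysScaffold, MaturePeptide, trim_to_mature
from csab.synthetic import GeneratorConfig, generate_corpus


def make_mature(
    nloop: str,
    loop12: str,
    loop23: str,
    loop34: str,
    loop45: str,
    loop56: str,
    tail: str,
    peptide_id: str = "pep",
    taxon_id: str | None = None,
) -> MaturePeptide:
    """Assemble a MaturePeptide directly from its seven scaffold segments."""
    segments = [nloop, loop12, loop23, loop34, loop45, loop56, tail]
    sequence = segments[0]
    for seg in segments[1:]:
        sequence += "C" + seg
    positions = []
    pos = len(nloop) + 1
    for seg in segments[1:6] + [None]:
        positions.append(pos)
        if seg is not None:
            pos += len(seg) + 1
    record = PeptideRecord(id=peptide_id, sequence=sequence, taxon_id=taxon_id)
    scaffold = CysScaffold.from_positions(sequence, tuple(positions))
    return MaturePeptide(
        record=record, scaffold=scaffold, mature_start=1, mature_end=len(sequence)
    )


@pytest.fixture(scope="session")
def small_corpus():
    """30+12 mature synthetic peptides with their truth table (seed 11)."""
    config = GeneratorConfig(n_gxgcp=30, n_xtcd=12, seed=11)
    records, truth = generate_corpus(config)
    return records, truth


@pytest.fixture(scope="session")
def small_matured(small_corpus):
    records, _ = small_corpus
    matured = [trim_to_mature(r) for r in records]
    assert all(m is not None for m in matured)
    return matured


@pytest.fixture(scope="session")
def plectasin_mature():
    mature = trim_to_mature(plectasin_record())
    assert mature is not None
    return mature
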