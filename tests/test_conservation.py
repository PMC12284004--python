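from __future__ import annotations

import itertools

import pytest

from csab.anchor_align import AlignParams, build_anchored_alignment
from csab.conservation import (
    CONSERVATIVE,
    GAP_STATUS,
    IDENTICAL,
    MECHANISM_RESIDUES,
    NONCONSERVATIVE,
    PLECTASIN_SEQUENCE,
    ReferenceResidueSet,
    conservation_status,
    plectasin_record,
    score_mechanism_residues,
)
from csab.io_formats import GAP, PeptideRecord
from csab.scaffold import trim_to_mature
from csab.subfamily import classify

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


class TestConservationStatus:
    @pytest.mark.parametrize(
        "expected, observed, status",
        [
            ("K", "K", IDENTICAL),
            ("Y", "R", NONCONSERVATIVE),  # aromatic → positive charge
            ("Y", "K", NONCONSERVATIVE),
            ("F", "Y", CONSERVATIVE),  # both aromatic
            ("K", "R", CONSERVATIVE),  # both positive
            ("I", "L", CONSERVATIVE),
            ("F", GAP, GAP_STATUS),
            ("F", "X", NONCONSERVATIVE),  # unknown residue
            ("H", "K", CONSERVATIVE),  # H is in both aromatic and positive
            ("H", "W", CONSERVATIVE),
        ],
    )
    def test_class_scheme(self, expected, observed, status):
        assert conservation_status(expected, observed) == status

    def test_total_over_all_canonical_pairs_and_gap(self):
        for e, o in itertools.product(CANONICAL, CANONICAL + "X" + GAP):
            assert conservation_status(e, o) in (
                IDENTICAL, CONSERVATIVE, NONCONSERVATIVE, GAP_STATUS,
            )

    def test_conservative_relation_is_symmetric(self):
        for e, o in itertools.combinations(CANONICAL, 2):
            assert (conservation_status(e, o) == CONSERVATIVE) == (
                conservation_status(o, e) == CONSERVATIVE
            )

    def test_blosum_mode_differs_but_is_total(self):
        assert conservation_status("F", "Y", scheme="blosum62") == CONSERVATIVE
        assert conservation_status("Y", "R", scheme="blosum62") == NONCONSERVATIVE


def _variant(position: int, residue: str, ident: str) -> PeptideRecord:
    seq = list(PLECTASIN_SEQUENCE)
    seq[position - 1] = residue
    return PeptideRecord(id=ident, sequence="".join(seq))


def _align(records):
    matured = [trim_to_mature(r) for r in records]
    assert all(m is not None for m in matured)
    return matured, build_anchored_alignment(matured, AlignParams())


class TestScoreMechanismResidues:
    def test_reference_scores_identical_against_itself(self):
        matured, aln = _align([plectasin_record(), _variant(21, "A", "copy")])
        report = score_mechanism_residues(aln, ReferenceResidueSet.plectasin())
        own = report.long[report.long["peptide"] == "plectasin"]
        assert len(own) == len(MECHANISM_RESIDUES) == 9
        assert (own["status"] == IDENTICAL).all()

    def test_planted_arginine_at_y25_is_nonconservative(self):
        records = [plectasin_record()] + [
            _variant(25, "R", f"v{i}") for i in range(5)
        ]
        matured, aln = _align(records)
        calls = [classify(m) for m in matured[1:]]
        report = score_mechanism_residues(
            aln, ReferenceResidueSet.plectasin(), calls
        )
        variants = report.long[
            (report.long["ref_position"] == 25)
            & (report.long["peptide"] != "plectasin")
        ]
        assert (variants["status"] == NONCONSERVATIVE).all()

    def test_planted_tyrosine_at_f2_is_conservative(self):
        records = [plectasin_record(), _variant(2, "Y", "fy")]
        _, aln = _align(records)
        report = score_mechanism_residues(aln, ReferenceResidueSet.plectasin())
        row = report.long[
            (report.long["ref_position"] == 2) & (report.long["peptide"] == "fy")
        ]
        assert row["status"].tolist() == [CONSERVATIVE]

    def test_tallies_conserve_peptide_count(self, small_matured):
        matured = small_matured + [trim_to_mature(plectasin_record())]
        aln = build_anchored_alignment(matured, AlignParams())
        report = score_mechanism_residues(aln, ReferenceResidueSet.plectasin())
        per_pos = report.long.groupby("ref_position").size()
        assert (per_pos == len(matured)).all()

    def test_missing_reference_row_raises(self, small_matured):
        aln = build_anchored_alignment(small_matured[:3], AlignParams())
        with pytest.raises(LookupError, match="plectasin"):
            score_mechanism_residues(aln, ReferenceResidueSet.plectasin())


class TestReferenceResidueSet:
    def test_plectasin_set_is_consistent(self):
        refset = ReferenceResidueSet.plectasin()
        assert refset.residues == MECHANISM_RESIDUES

    def test_for_record_rejects_mismatch(self):
        with pytest.raises(ValueError, match="expected"):
            ReferenceResidueSet.for_record(_variant(2, "A", "bad"))
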