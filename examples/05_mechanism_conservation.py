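"""Score conservation of the nine plectasin lipid II-binding residues.

The mechanism residues (F2, H18, K20, I22, K23, Y25, K26, Y29, Y40) are
mapped onto alignment columns through the plectasin row, and every
peptide's residue at each column is scored identical / conservative /
nonconservative / gap under a transparent residue-class scheme.
"""

from csab import (
    AlignParams,
    GeneratorConfig,
    ReferenceResidueSet,
    build_anchored_alignment,
    classify,
    generate_corpus,
    plectasin_record,
    score_mechanism_residues,
    trim_to_mature,
)

records, _ = generate_corpus(GeneratorConfig(n_gxgcp=88, n_xtcd=35, seed=1))
matured = [trim_to_mature(r) for r in records]
calls = [classify(m) for m in matured]
matured.append(trim_to_mature(plectasin_record()))

aln = build_anchored_alignment(matured, AlignParams())
report = score_mechanism_residues(aln, ReferenceResidueSet.plectasin(), calls)

print("per-position conserved fraction (identical or conservative), GXGCP rows:")
for pos, expected in ReferenceResidueSet.plectasin().residues:
    frac = report.fraction(pos, "identical", "GXGCP") + report.fraction(
        pos, "conservative", "GXGCP"
    )
    print(f"  {expected}{pos:>2}: {100 * frac:5.1f}%")
# K23 stands out as poorly conserved — the one mechanism residue the
# family does not maintain — while the XTCD group replaces the aromatic
# Y25/Y40 with positively charged residues (run with subfamily='XTCD').
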