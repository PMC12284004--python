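# csab — comparative analysis of CSαβ defensin scaffolds

Defensins of the cysteine-stabilised α-helix/β-sheet (CSαβ) fold are
small antimicrobial peptides held together by three disulphide bonds
between six conserved cysteines. The fold spans kingdoms: it occurs in
fungi, molluscs, arachnids and insects, and also in bacterial
defensin-like bacteriocins such as actifensin. Comparative analysis of
these peptides splits the family into two structural subfamilies around
the first scaffold cysteine (C1):

* **GXGCP** — a short N-terminal loop ending Gly–X–Gly (X aromatic)
  immediately before C1, usually with Pro at C1+1
  (actifensin: Gly1-Phe2-Gly3-Cys4-Pro5). Trans-kingdom: bacteria plus
  ancient invertebrates and fungi.
* **XTCD** — an extended N-terminal loop ending Thr at C1−1 with Asp at
  C1+1, typically followed by an aliphatic pair (e.g. Leu-Leu).
  Eukaryote-only, concentrated in recent insect orders (beetles, flies,
  true bugs, wasps, moths).

`csab` is a Python library (plus a thin `csab` command-line tool) for
running this analysis end to end, offline and reproducibly:

1. **Scaffold detection** — exhaustive, window-constrained search for the
   six-cysteine subset C1…C6 whose inter-cysteine spacings match the CSαβ
   pattern (plectasin numbering: C4, C15, C19, C30, C37, C39), with
   deterministic tie-breaking.
2. **Maturation** — scaffold-anchored trimming of precursors to mature
   peptides.
3. **Cysteine-anchored alignment** — the seven inter-anchor segments are
   aligned independently (N-loop right-justified toward C1; interior
   loops by center-star alignment with BLOSUM62 and affine gaps) and
   concatenated around six all-cysteine anchor columns.
4. **Subfamily classification** — a 2-of-3 evidence vote per subfamily
   (loop length, N-terminal motif, residue(s) after C1); the conserved
   histidine preceding C3 is reported as evidence, never used for
   labelling.
5. **Mechanism-residue conservation** — the nine plectasin residues
   implicated in lipid II binding (F2, H18, K20, I22, K23, Y25, K26,
   Y29, Y40) are mapped onto alignment columns and each peptide is scored
   identical / conservative / nonconservative / gap under a transparent
   residue-class scheme (BLOSUM62>0 mode available).
6. **Taxonomic spread** — subfamily counts aggregated up a supplied
   lineage table, with a trans-kingdom flag and a tree annotation using
   the fixed colour convention GXGCP→yellow, XTCD→blue.

A synthetic-corpus generator (`csab.synthetic`) produces 34–60-residue
six-cysteine peptides with both subfamilies' motifs planted at the
family's observed frequencies, together with a truth table, lineage
table and taxonomy tree — so every stage is testable with no downloads.

## Worked example

```python
from csab import (GeneratorConfig, classify, generate_corpus,
                  summarize_calls, trim_to_mature)

records, truth = generate_corpus(GeneratorConfig(n_gxgcp=88, n_xtcd=35, seed=1))
calls = [classify(trim_to_mature(r)) for r in records]
summary = summarize_calls(calls)
print(summary["counts"])
print(summary["fractions_pct"])
print(summary["prec3_his"]["overall"])
```

prints

```
{'GXGCP': 83, 'XTCD': 35, 'UNCLASSIFIED': 5}
{'GXGCP': 67.5, 'XTCD': 28.5, 'UNCLASSIFIED': 4.1}
{'count': 98, 'of': 123}
```

A 123-peptide corpus was generated in the family's 88:35 composition at
its observed motif frequencies (only ~59% of GXGCP-type peptides carry
the full GXG motif, ~91% the Pro). Classification recovers 83 of the 88
planted GXGCP peptides — the handful lacking both GXG and Pro fall to
UNCLASSIFIED rather than being mislabelled — all 35 XTCD peptides, and
finds the conserved pre-C3 histidine in 98/123 peptides (planted at
0.82). With all motif fidelities at 1.0 the recovered GXGCP fraction is
exactly 71.5%.

The `examples/` directory has one short script per capability
(generation, scaffold/trimming, anchored alignment, classification,
conservation, taxonomy), each printing what it computes. The same
stages are available from the shell:

```bash
csab generate --out corpus/ --seed 1
csab run --in corpus/corpus.fasta --lineage corpus/lineage.tsv \
         --tree corpus/taxonomy.nwk --out results/ --seed 1
```

## Layout

```
src/csab/          library (io_formats, scaffold, anchor_align, subfamily,
                   conservation, taxonomy, synthetic, pipeline, cli)
examples/          narrative scripts, one per capability
tests/             pytest suite with brute-force oracles
scripts/           acceptance script
docs/methods.md    models, parameters, numerical choices, limitations
```
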