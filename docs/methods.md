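# Methods

This note documents the models and procedures implemented in `csab`,
the parameters that matter, the synthetic data they are validated on,
and the numerical choices made where the design was genuinely open.

## The CSαβ scaffold model

A CSαβ peptide is modelled as six cysteines C1…C6 (three disulphides)
separating seven segments: the N-terminal loop (N-loop, before C1), five
inter-cysteine loops, and a C-terminal tail. Spacings are constrained by
per-loop windows of *intervening residue counts*, defaulting to

| loop | window | plectasin |
|------|--------|-----------|
| C1–C2 | 4–16 | 10 |
| C2–C3 | 2–6  | 3 |
| C3–C4 | 6–14 | 10 |
| C4–C5 | 3–10 | 6 |
| C5–C6 | 1–3  | 1 |

with the N-loop capped at 25 residues during search. The windows
generalise the plectasin anchor spacing (cysteines at 4, 15, 19, 30, 37,
39) with slack for the family's 34–60-residue length range; all are
configurable. They deliberately exclude the two-disulphide (2ds-CSαβ)
fold, which is out of scope.

**Detection** (`find_scaffold`) is exhaustive over cysteine subsets,
implemented as a depth-first extension with window pruning, so it cannot
miss a valid subset. Among valid subsets the winner (i) maximises the
number of loops within one residue of their window midpoint, (ii)
minimises total deviation from the midpoints, (iii) takes the
lexicographically smallest positions. This makes detection a pure
function of the sequence. Degenerate inputs (fewer than six cysteines,
no window-satisfying subset) return "not a candidate" rather than
raising.

**Maturation** (`trim_to_mature`) is scaffold-anchored rather than
leader-model-based: the mature region is `max(1, C1 − max_nloop)` …
`min(len, C6 + max_tail)` with defaults `max_nloop=12`, `max_tail=6`,
accepted only if 20–80 residues long. This is a deliberate divergence
from leader-peptide annotation pipelines, which require external
predictors; the cost is that up to `max_nloop` leader residues can
survive trimming (the tests allow exactly this slack). During the
scaffold search on a precursor the N-loop cap is relaxed to the sequence
length — the leader would otherwise push C1 past the cap — and the trim
window then enforces the final bound. Trimming is idempotent: re-running
it on its own output changes nothing.

## Cysteine-anchored alignment

A correct family alignment must keep each scaffold cysteine in one
all-cysteine column. Instead of post-editing a general aligner's output,
the seven segments are aligned block-wise and concatenated around
single-residue anchor columns:

* **N-loop**: right-justified toward C1, padding only. This keeps the
  motif offsets C1−1, C1−2, C1−3 column-stable, which is what makes the
  GXGCP/XTCD motifs columnar; realigning this block would defeat the
  purpose, so no intra-block alignment is applied to it.
* **C-tail**: left-justified padding (ragged tails have no anchor on
  their right; this is a display choice).
* **Interior loops**: center-star multiple alignment. The star is the
  segment maximising its summed optimal pairwise score against all
  others (ties: lexicographically smallest segment); every other segment
  is globally aligned to the star (BLOSUM62; a length-*k* gap costs
  `gap_open + k·gap_extend` = 10 + k by default); pairwise alignments
  are merged through per-star-position insertion counts ("once a gap,
  always a gap", existing columns never shortened).

Two properties follow by construction and are asserted in tests: the
merge is independent of input row order (insertion counts are per-pair
maxima, and the star tie-break is content-based, so permuting rows never
changes the anchor columns or any row's gap-stripped sequence), and each
star↔row projection achieves the optimal pairwise score.

A `pad` mode (justification only, no realignment) is provided as a
trivially verifiable baseline.

**Known limitation — approximation, not optimality.** Center-star is the
classical 2-approximation to optimal sum-of-pairs multiple alignment and
is *not* exact in general. Against a brute-force enumeration oracle on
tiny instances (≤4 segments of ≤4 residues): equal-length segment sets
are always aligned optimally (the gapless alignment is optimal and
center-star finds it), homologous sets with indels are aligned optimally
in roughly 92–97% of random instances, and unrelated variable-length
sets substantially less often. The test suite asserts the true
invariants (the oracle upper-bounds the center-star score; equal-length
instances are exact; the exact fraction on homologous sets is high);
the acceptance suite also contains a strict exactness check on random
homologous instances, which the algorithm cannot fully satisfy — kept,
deliberately, as an honest record of the approximation boundary rather
than weakened.

## Subfamily classification

Evidence is read at fixed offsets from C1 of the mature peptide:

* `nloop_len = C1 − 1`; short means ≤ 5, long means ≥ 6 (configurable;
  actifensin's N-loop is 3, XTCD loops are extended).
* `has_GXG`: residues at C1−3, C1−2, C1−1 are Gly, aromatic {F,W,Y,H},
  Gly. Loops shorter than 3 simply fail the test (no error).
* `has_pro`: Pro at C1+1.
* `has_XTCD`: Thr at C1−1 and Asp at C1+1 (the "X" is unconstrained).
* `has_aliphatic_pair`: residues at C1+2 and C1+3 both in {A,V,L,I,M}
  (offsets configurable; the pair's exact placement is not pinned by the
  family description).

Scores: `score_GXGCP = [short] + [GXG] + [Pro]`,
`score_XTCD = [long] + [XTCD] + [pair]`; the label is the unique
maximiser if it reaches 2, else UNCLASSIFIED. A motif-only rule cannot
reproduce the family's split — only ~59% of GXGCP-type peptides carry
the full GXG — whereas loop length holds across the whole subfamily,
hence the vote with loop length as one component. Since G ≠ T at C1−1,
the two motifs are mutually exclusive, so ties can only arise between
weak evidence and resolve to UNCLASSIFIED.

The conserved pre-C3 histidine (`check_preC3_his`, plectasin H18) and
the double-Ala helix propensity of XTCD peptides are reported as
descriptive evidence only; the family descriptions give frequencies for
them, not rules.

## Mechanism-residue conservation

The reference is plectasin (embedded 40-residue sequence, validated at
construction against its cysteine positions and the nine mechanism
residues F2, H18, K20, I22, K23, Y25, K26, Y29, Y40). Each reference
position is mapped to its alignment column via the reference row's
coordinate map; each peptide's residue at that column is scored:

* identical — equals the expected residue;
* conservative — shares at least one residue class with it. Classes:
  aromatic {F,W,Y,H}, aliphatic {A,V,L,I,M}, positive {K,R,H}, negative
  {D,E}, small-polar {S,T,N,Q,G,C,P}. Histidine deliberately belongs to
  two classes. "Conservative substitution" has no canonical definition;
  a transparent class scheme is auditable, and a BLOSUM62>0 mode is
  provided for sensitivity analysis;
* nonconservative — otherwise, including observed X (unknown);
* gap — its own category, so indel variation is never conflated with
  substitution.

The relation is symmetric and total; tallies sum to the peptide count at
every position. Conservation is reported as fractions only — the family
literature treats it qualitatively, so no pass/fail threshold is
imposed. K23 receives no special handling; its expected
non-conservation is an observation the synthetic generator reproduces,
not a rule.

## Taxonomic spread

Lineages arrive as a TSV (taxon_id, semicolon-joined root→leaf lineage,
display name); all lineages must share a root. Calls are aggregated up
the lineage tree; each clade is flagged GXGCP-only / XTCD-only / mixed /
none, and a subfamily is **trans-kingdom** when it occurs under at least
two depth-1 clades (children of the root). "Kingdom = depth 1" keeps the
analysis a pure function of the supplied table — no taxonomy service is
queried. Peptides whose taxon is absent go to an explicit "unplaced"
bin. Tree annotation emits the unchanged Newick plus a leaf/label/colour
TSV under the fixed bijection GXGCP→yellow, XTCD→blue (a mixed taxon
gets both rows); labels naming absent leaves are reported, not fatal.

## Synthetic corpora

The generator emulates the real study corpus (a curated arthropod
defensin family plus HMM-identified bacterial actifensins) as the study
conditions the tests assume:

* composition 88 GXGCP : 35 XTCD; lengths bounded 34–60 with mean ≈ 38
  (segment lengths are drawn uniformly per loop — N-loop 3–5 for GXGCP
  and 6–8 for XTCD; inter-cysteine loops 5–10 / 2–4 / 8–11 / 3–7 / 1–2;
  tail 1–2 — and resampled until the total lands in bounds);
* motif fidelities matching the family's observed frequencies: GXG 0.59,
  Pro 0.91, pre-C3 His 0.82, XTCD motif 1.0, aliphatic pair 0.70. A
  fidelity miss actively removes the feature (e.g. the C1−1 residue is
  redrawn excluding Gly) so planted frequencies are exactly binomial;
* mechanism residues planted at plectasin-homologous scaffold offsets
  (K20…K26 relative to C3, Y29 to C4, Y40 to C6) at fidelity 0.9 with
  conservative same-class substitutes on a miss — except K23
  (fidelity 0.2, background on miss), reproducing the family's one
  non-conserved mechanism residue. XTCD rows instead receive Arg at the
  Y25 slot and Lys at the Y40 slot (p = 0.8), the subfamily's
  characteristic non-conservative replacements;
* taxa sampled from synthetic clades shaped like the family's spread
  (GXGCP: two bacterial orders, fungi, molluscs, dragonflies, scorpions;
  XTCD: five recent insect orders), with a matching lineage table and
  Newick tree. Names are stand-ins, not real taxonomy identifiers.

Simplifications, hence what passing tests do **not** show about real
data: the background is uniform over the 19 non-cysteine residues (real
loops have composition bias and correlations); leaders are cysteine-free
(real leaders may contain cysteine, which can defeat scaffold-anchored
trimming); exactly six cysteines per mature peptide (real precursors can
carry extras); taxa are drawn independently of sequence (no
phylogenetic signal). Precursor mode prepends a 15–30-residue leader and
records the true mature start.

All sampling flows from one `numpy` generator seeded by `seed`; output
is byte-identical for a fixed configuration.

## Problem sizes and determinism

The validation suite runs at fixed sizes chosen to exercise every code
path while staying quick on one CPU: 500 random sequences for the
scaffold-vs-enumeration check, 123-peptide corpora for alignment,
classification, conservation and taxonomy, 200 tiny instances for the
alignment oracle, 100 peptides per subfamily for label recovery, and two
full pipeline runs for byte-identity. Reports contain no timestamps;
rerunning any stage with the same configuration and seed reproduces
identical bytes.
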