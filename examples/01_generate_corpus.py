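"""Generate a synthetic CSαβ defensin corpus with planted ground truth.

The generator emulates a mixed family corpus: 88 GXGCP-type peptides
(short N-loop, Gly-aromatic-Gly motif, Pro after C1) and 35 XTCD-type
peptides (extended N-loop ending Thr, Asp after C1), with the family's
observed motif frequencies and 34-60-residue lengths.
"""

from csab import GeneratorConfig, generate_corpus

records, truth = generate_corpus(GeneratorConfig(n_gxgcp=88, n_xtcd=35, seed=1))

lengths = [len(r) for r in records]
print(f"peptides: {len(records)}")
print(f"lengths:  {min(lengths)}-{max(lengths)}, mean {sum(lengths)/len(lengths):.1f}")
print(f"true GXGCP fraction: {100 * (truth.subfamily == 'GXGCP').mean():.1f}%")
print("first record:", records[0].id, records[0].sequence)
print(truth[["id", "subfamily", "taxon_id", "nloop_len", "gxg", "pro", "his"]].head())
# Each truth row records what was planted, so downstream detection and
# classification can be scored against known ground truth.
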