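from __future__ import annotations

import io

import numpy as np
import pytest
from scipy import stats

from csab.io_formats import write_fasta
from csab.scaffold import find_scaffold, trim_to_mature
from csab.subfamily import classify
from csab.synthetic import (
    GeneratorConfig,
    generate_corpus,
    generate_precursors,
    synthetic_lineage_table,
    synthetic_taxonomy_newick,
)
from csab.io_formats import newick_leaf_names


def fasta_bytes(records) -> str:
    buf = io.StringIO()
    for r in records:
        buf.write(f">{r.id}\n{r.sequence}\n")
    return buf.getvalue()


class TestGenerateCorpus:
    def test_fixed_seed_is_byte_identical(self):
        a, _ = generate_corpus(GeneratorConfig(seed=7))
        b, _ = generate_corpus(GeneratorConfig(seed=7))
        assert fasta_bytes(a) == fasta_bytes(b)

    def test_different_seed_differs(self):
        a, _ = generate_corpus(GeneratorConfig(seed=7))
        b, _ = generate_corpus(GeneratorConfig(seed=8))
        assert fasta_bytes(a) != fasta_bytes(b)

    def test_every_mature_peptide_passes_scaffold_detection(self, small_corpus):
        records, truth = small_corpus
        for rec, (_, row) in zip(records, truth.iterrows()):
            scaffold = find_scaffold(rec.sequence)
            assert scaffold is not None
            assert scaffold.nloop == rec.sequence[: row["nloop_len"]]

    def test_exactly_six_cysteines(self, small_corpus):
        records, _ = small_corpus
        assert all(r.sequence.count("C") == 6 for r in records)

    def test_full_fidelity_gxgcp_all_classified(self):
        config = GeneratorConfig(
            n_gxgcp=10, n_xtcd=0, seed=7,
            p_gxg=1.0, p_pro=1.0, p_his=1.0,
        )
        records, _ = generate_corpus(config)
        assert len(records) == 10
        for rec in records:
            assert classify(trim_to_mature(rec)).label == "GXGCP"

    def test_length_mean_near_target(self):
        records, _ = generate_corpus(GeneratorConfig(seed=3))
        lengths = [len(r) for r in records]
        config = GeneratorConfig()
        assert min(lengths) >= config.length_bounds[0]
        assert max(lengths) <= config.length_bounds[1]
        assert abs(np.mean(lengths) - config.target_mean_length) <= 2

    def test_planted_feature_frequencies_match_fidelities(self):
        config = GeneratorConfig(n_gxgcp=150, n_xtcd=100, seed=5)
        _, truth = generate_corpus(config)
        checks = [
            (truth[truth.subfamily == "GXGCP"]["gxg"], config.p_gxg),
            (truth[truth.subfamily == "GXGCP"]["pro"], config.p_pro),
            (truth["his"], config.p_his),
            (truth[truth.subfamily == "XTCD"]["aliphatic_pair"], config.p_aliphatic_pair),
        ]
        for observed, p in checks:
            n, k = len(observed), int(observed.sum())
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= k <= hi

    def test_infeasible_length_bounds_rejected_before_output(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(length_bounds=(5, 10))

    def test_mixture_echoes_configured_composition(self):
        _, truth = generate_corpus(GeneratorConfig(n_gxgcp=88, n_xtcd=35, seed=1))
        frac = (truth.subfamily == "GXGCP").mean()
        assert round(100 * frac, 1) == 71.5


class TestGeneratePrecursors:
    def test_leaders_are_cysteine_free_and_recorded(self):
        config = GeneratorConfig(n_gxgcp=15, n_xtcd=5, seed=9)
        precursors, truth = generate_precursors(config)
        for rec, (_, row) in zip(precursors, truth.iterrows()):
            start = int(row["mature_start"])
            assert "C" not in rec.sequence[: start - 1]
            lo, hi = config.leader_length_range
            assert lo + 1 <= start <= hi + 1

    def test_trim_recovers_mature_start_within_slack(self):
        config = GeneratorConfig(n_gxgcp=15, n_xtcd=5, seed=9)
        precursors, truth = generate_precursors(config)
        max_nloop = 12
        for rec, (_, row) in zip(precursors, truth.iterrows()):
            mature = trim_to_mature(rec, max_nloop=max_nloop)
            assert mature is not None
            assert abs(mature.mature_start - int(row["mature_start"])) <= max_nloop

    def test_zero_length_leader_equals_mature(self):
        config = GeneratorConfig(n_gxgcp=5, n_xtcd=0, seed=2, leader_length_range=(0, 0))
        precursors, _ = generate_precursors(config)
        matures, _ = generate_corpus(config)
        assert [p.sequence for p in precursors] == [m.sequence for m in matures]


class TestTaxonomyArtifacts:
    def test_lineage_table_covers_both_kingdoms(self):
        table = synthetic_lineage_table()
        kingdoms = {table.lineage(t)[1] for t in table.rows}
        assert kingdoms == {"Bacteria", "Eukaryota"}

    def test_newick_leaves_match_lineage_taxa(self):
        leaves = set(newick_leaf_names(synthetic_taxonomy_newick()))
        assert leaves == set(synthetic_lineage_table().rows)
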