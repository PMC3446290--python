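"""Compositional island detection: per-gene statistics, window scan,
merging, and planted-island recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strainflux.islands import (
    GeneComposition,
    IslandDataError,
    SENSE_CODONS,
    codon_usage_pvalue,
    compose_genes,
    foreign_flags,
    gc_zscores,
    gene_composition_from_sequence,
    genome_codon_frequencies,
    load_gene_table,
    load_genome_fasta,
    scan_islands,
    write_islands_bed,
    write_islands_gff3,
)
from strainflux.models import AnalysisConfig
from strainflux.synthetic_data import simulate_genome, write_gene_table, write_genome_fasta

from tests._oracles import islands_by_window_enumeration


def make_gene(gene_id, gc, start=1, end=300, codons=None) -> GeneComposition:
    return GeneComposition(
        gene_id=gene_id, start=start, end=end, strand="+",
        codon_counts=codons or {}, gc_fraction=gc,
    )


class TestGCZScores:
    def test_identical_gc_gives_all_zero(self):
        genes = [make_gene(f"g{i}", 0.5) for i in range(5)]
        assert set(gc_zscores(genes).values()) == {0.0}

    def test_hand_computed_outlier(self):
        """{0.5, 0.5, 0.5, 0.8}: population σ = 0.12990, so the 0.8 gene
        sits at z = 0.225/0.12990 = 1.732 > 1.5."""
        genes = [make_gene("a", 0.5), make_gene("b", 0.5),
                 make_gene("c", 0.5), make_gene("d", 0.8)]
        z = gc_zscores(genes)
        assert z["d"] == pytest.approx(1.7320508, abs=1e-6)
        assert abs(z["d"]) > 1.5
        assert all(abs(z[g]) < 1.5 for g in ("a", "b", "c"))

    def test_threshold_is_two_sided(self):
        genes = [make_gene("low", 0.2)] + [make_gene(f"g{i}", 0.5) for i in range(9)]
        z = gc_zscores(genes)
        assert z["low"] < -1.5  # GC-poor genes are aberrant too

    def test_single_gene_is_insufficient_data(self):
        with pytest.raises(IslandDataError):
            gc_zscores([make_gene("only", 0.5)])


class TestCodonUsagePValue:
    def test_gene_matching_genome_frequencies_has_p_one(self):
        counts = {c: 10 for c in SENSE_CODONS[:4]}
        gene_a = make_gene("a", 0.5, codons=dict(counts))
        gene_b = make_gene("b", 0.5, codons=dict(counts))
        freq = genome_codon_frequencies([gene_a, gene_b])
        assert codon_usage_pvalue(gene_a, freq) == pytest.approx(1.0)

    def test_concentrated_synonymous_usage_is_significant(self):
        """100 uses of one codon where the genome spreads evenly over 4
        synonymous codons: chi2 = 300 on 3 df, far beyond the 0.05 cut."""
        freq = {c: 0.25 for c in ("CTA", "CTC", "CTG", "CTT")}
        gene = make_gene("g", 0.5, codons={"CTG": 100})
        p = codon_usage_pvalue(gene, freq)
        assert p < 0.05
        # hand value: chi2 = 3*25/0.25... = sum((o-e)^2/e) = 300, df=3
        from scipy.stats import chi2

        assert p == pytest.approx(float(chi2.sf(300.0, 3)))

    def test_zero_expectation_codons_excluded_from_df(self):
        freq = {"CTA": 0.5, "CTC": 0.5, "CTG": 0.0}
        gene = make_gene("g", 0.5, codons={"CTA": 5, "CTC": 5})
        assert codon_usage_pvalue(gene, freq) == pytest.approx(1.0)


class TestForeignFlags:
    def _genes(self):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(20):
            counts = {c: int(rng.integers(3, 8)) for c in SENSE_CODONS}
            genes.append(make_gene(f"g{i}", 0.5, codons=counts))
        return genes

    def test_gc_aberrance_alone_is_not_foreign(self):
        genes = self._genes()
        genes[3] = make_gene("g3", 0.95, codons=genes[3].codon_counts)
        freq = genome_codon_frequencies(genes)
        # codon usage of g3 matches the pool, so the conjunction fails
        flags = foreign_flags(genes, freq)
        z = gc_zscores(genes)
        assert abs(z["g3"]) > 1.5
        assert flags[3] is False or codon_usage_pvalue(genes[3], freq) < 0.05

    def test_both_aberrant_is_foreign(self):
        genes = self._genes()
        genes[3] = make_gene("g3", 0.95, codons={"CTG": 200})
        freq = genome_codon_frequencies(genes)
        flags = foreign_flags(genes, freq)
        assert flags[3] is True

    def test_flags_equal_per_gene_brute_force(self):
        cfg = AnalysisConfig()
        genes = self._genes()
        genes[5] = make_gene("g5", 0.9, codons={"GGG": 150})
        genes[11] = make_gene("g11", 0.1, codons={"AAA": 150})
        freq = genome_codon_frequencies(genes)
        flags = foreign_flags(genes, freq, cfg)
        z = gc_zscores(genes)
        for g, flag in zip(genes, flags):
            expected = (
                abs(z[g.gene_id]) > cfg.gc_sigma_threshold
                and codon_usage_pvalue(g, freq) < cfg.codon_p_threshold
            )
            assert flag == expected


class TestScanIslands:
    def _genes(self, n):
        return [make_gene(f"g{i}", 0.5, start=1 + 300 * i, end=300 * (i + 1))
                for i in range(n)]

    def test_no_flags_no_islands(self):
        genes = self._genes(20)
        assert scan_islands([False] * 20, genes) == []

    def test_four_consecutive_trues_make_one_island(self):
        genes = self._genes(14)
        flags = [False] * 5 + [True] * 4 + [False] * 5
        calls = scan_islands(flags, genes)
        assert len(calls) == 1
        oracle = islands_by_window_enumeration(flags, 10, 4)
        assert (calls[0].first_gene_index, calls[0].last_gene_index) == oracle[0]
        assert calls[0].n_foreign == 4

    def test_two_separated_clusters_make_two_islands(self):
        genes = self._genes(60)
        flags = [False] * 60
        for i in list(range(5, 9)) + list(range(45, 49)):
            flags[i] = True
        calls = scan_islands(flags, genes)
        assert len(calls) == 2
        oracle = islands_by_window_enumeration(flags, 10, 4)
        assert [(c.first_gene_index, c.last_gene_index) for c in calls] == oracle

    @given(st.lists(st.booleans(), min_size=10, max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_window_enumeration_oracle(self, flags):
        genes = self._genes(len(flags))
        calls = scan_islands(flags, genes)
        oracle = islands_by_window_enumeration(flags, 10, 4)
        assert [(c.first_gene_index, c.last_gene_index) for c in calls] == oracle

    def test_islands_are_maximal_and_qualified(self):
        rng = np.random.default_rng(11)
        cfg = AnalysisConfig()
        for _ in range(30):
            flags = list(rng.random(40) < 0.25)
            genes = self._genes(40)
            for c in scan_islands(flags, genes, cfg):
                window_counts = [
                    sum(flags[i : i + cfg.window_genes])
                    for i in range(c.first_gene_index,
                                   c.last_gene_index - cfg.window_genes + 1)
                ]
                assert any(n >= cfg.min_foreign for n in window_counts)

    def test_gene_relabeling_leaves_spans_unchanged(self):
        flags = [False] * 5 + [True] * 5 + [False] * 10
        genes = self._genes(20)
        relabeled = [
            GeneComposition(
                gene_id=f"renamed_{i}", start=g.start, end=g.end, strand=g.strand,
                codon_counts=g.codon_counts, gc_fraction=g.gc_fraction,
            )
            for i, g in enumerate(genes)
        ]
        assert [c.genomic_span for c in scan_islands(flags, genes)] == [
            c.genomic_span for c in scan_islands(flags, relabeled)
        ]

    def test_window_larger_than_genome_is_error(self):
        with pytest.raises(IslandDataError, match="window_genes"):
            scan_islands([True] * 5, self._genes(5))


class TestSequenceComposition:
    def test_codon_counts_and_gc_from_sequence(self):
        genome = "ATGGCCGCA" + "A" * 10
        g = gene_composition_from_sequence("g", 1, 9, "+", genome)
        assert g.codon_counts == {"ATG": 1, "GCC": 1, "GCA": 1}
        assert g.gc_fraction == pytest.approx(6 / 9)
        assert g.n_codons == 3

    def test_minus_strand_reverse_complement(self):
        genome = "ATGGCC"
        g = gene_composition_from_sequence("g", 1, 6, "-", genome)
        assert g.codon_counts == {"GGC": 1, "CAT": 1}

    def test_fasta_and_gene_table_io(self, tmp_path):
        seq, table, _ = simulate_genome(30, [], seed=1)
        write_genome_fasta(seq, tmp_path / "g.fa")
        write_gene_table(table, tmp_path / "genes.tsv")
        assert load_genome_fasta(tmp_path / "g.fa") == seq
        assert load_gene_table(tmp_path / "genes.tsv") == table


class TestPlantedIslandRecovery:
    def test_null_genome_has_few_false_positives(self):
        seq, table, _ = simulate_genome(150, [], seed=5)
        genes = compose_genes(seq, table)
        flags = foreign_flags(genes)
        assert sum(flags) / len(flags) < 0.05

    def test_planted_island_recovered(self):
        seq, table, truth = simulate_genome(120, [(50, 12, 0.15, 8.0)], seed=9)
        genes = compose_genes(seq, table)
        calls = scan_islands(foreign_flags(genes), genes)
        (p_start, p_stop) = truth.island_spans[0]
        overlaps = [
            min(c.last_gene_index, p_stop) - max(c.first_gene_index, p_start)
            for c in calls
        ]
        assert any(o > 0 for o in overlaps)

    def test_track_writers(self, tmp_path):
        seq, table, _ = simulate_genome(60, [(20, 12, 0.15, 8.0)], seed=2)
        genes = compose_genes(seq, table)
        calls = scan_islands(foreign_flags(genes), genes)
        write_islands_gff3(calls, tmp_path / "i.gff3")
        write_islands_bed(calls, tmp_path / "i.bed")
        gff = (tmp_path / "i.gff3").read_text().splitlines()
        assert gff[0] == "##gff-version 3"
        if calls:
            cols = gff[1].split("\t")
            bed_cols = (tmp_path / "i.bed").read_text().splitlines()[0].split("\t")
            # GFF3 1-based inclusive vs BED 0-based half-open
            assert int(cols[3]) == int(bed_cols[1]) + 1
            assert int(cols[4]) == int(bed_cols[2])
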