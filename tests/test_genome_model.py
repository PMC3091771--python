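"""Gene-model merging, intergenic halving, promoters, intronless counting."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from imprintcons import io as io_mod
from imprintcons.genome_model import (
    GeneModel,
    TranscriptRecord,
    build_gene_models,
    count_intronless,
    merge_transcripts,
    partition_intergenic,
    promoter_of,
)

from oracles import per_base_gene_labels, random_gene_fixture


def tx(gene_id="g", chrom="chr1", strand="+", exons=((0, 100),), cds=None):
    return TranscriptRecord(
        gene_id, chrom, strand, exons[0][0], exons[-1][1], tuple(exons),
        cds_start=cds[0] if cds else None, cds_end=cds[1] if cds else None)


class TestMergeTranscripts:
    def test_union_of_two_overlapping_transcripts(self):
        a = tx(exons=((100, 200), (400, 500)))
        b = tx(exons=((150, 250), (450, 600)))
        m = merge_transcripts([a, b])
        assert m.span == (100, 600)
        assert m.merged_exons == [(100, 250), (400, 600)]
        assert m.introns == [(250, 400)]

    def test_single_exon_gene_is_intronless(self):
        m = merge_transcripts([tx(exons=((10, 500),))])
        assert m.introns == []
        assert m.is_intronless

    def test_mixed_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            merge_transcripts([tx(strand="+"), tx(strand="-")])

    def test_mixed_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            merge_transcripts([tx(chrom="chr1"), tx(chrom="chr2")])

    def test_mixed_gene_id_rejected(self):
        with pytest.raises(ValueError, match="gene ids"):
            merge_transcripts([tx(gene_id="a"), tx(gene_id="b")])

    def test_cds_union_is_largest_coding_cover(self):
        a = tx(exons=((0, 100), (200, 300)), cds=(50, 250))
        b = tx(exons=((0, 100), (200, 300)), cds=(20, 280))
        m = merge_transcripts([a, b])
        assert m.merged_coding == [(20, 100), (200, 280)]

    def test_merge_is_idempotent(self, rng):
        for _ in range(25):
            genes, _ = random_gene_fixture(rng, chrom_length=5000, max_genes=3)
            for g in genes:
                rec = TranscriptRecord(
                    g.gene_id, g.chrom, g.strand, g.start, g.end,
                    tuple(g.merged_exons),
                    cds_start=g.merged_coding[0][0] if g.merged_coding else None,
                    cds_end=g.merged_coding[-1][1] if g.merged_coding else None)
                m = merge_transcripts([rec, rec])
                assert m.span == g.span
                assert m.merged_exons == list(g.merged_exons)

    def test_intron_tiling_sums_to_span(self, rng):
        for _ in range(50):
            genes, _ = random_gene_fixture(rng)
            for g in genes:
                exon_len = sum(e - s for s, e in g.merged_exons)
                intron_len = sum(e - s for s, e in g.introns)
                assert exon_len + intron_len == g.length


def gene(gid, start, end, chrom="chr1", strand="+"):
    return GeneModel(gid, chrom, strand, start, end, [(start, end)], [])


class TestPartitionIntergenic:
    def test_halving_between_two_genes(self):
        regions = partition_intergenic([gene("g1", 0, 100), gene("g2", 200, 300)], 400)
        got = [(r.start, r.end, r.assigned_gene_id) for r in regions]
        assert got == [(100, 150, "g1"), (150, 200, "g2"), (300, 400, "g2")]

    def test_adjacent_genes_leave_no_gap(self):
        regions = partition_intergenic([gene("g1", 0, 100), gene("g2", 100, 200)], 200)
        assert regions == []

    def test_single_gene_owns_both_flanks(self):
        regions = partition_intergenic([gene("g1", 100, 200)], 500)
        got = [(r.start, r.end, r.assigned_gene_id, r.side) for r in regions]
        assert got == [(0, 100, "g1", "upstream"), (200, 500, "g1", "downstream")]

    def test_odd_gap_extra_base_to_left_gene(self):
        regions = partition_intergenic([gene("g1", 0, 10), gene("g2", 15, 20)], 20)
        got = [(r.start, r.end, r.assigned_gene_id) for r in regions]
        assert got == [(10, 13, "g1"), (13, 15, "g2")]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            partition_intergenic([gene("g2", 200, 300), gene("g1", 0, 100)], 400)

    def test_overlapping_spans_yield_empty_gap(self):
        regions = partition_intergenic(
            [gene("g1", 0, 150), gene("g2", 100, 300)], 400)
        got = [(r.start, r.end, r.assigned_gene_id) for r in regions]
        assert got == [(300, 400, "g2")]

    def test_partition_conserves_chromosome_length(self, rng):
        for _ in range(50):
            genes, chrom_length = random_gene_fixture(rng)
            genes = sorted(genes, key=lambda g: (g.start, g.end))
            regions = partition_intergenic(genes, chrom_length)
            span_len = sum(g.length for g in genes)
            inter_len = sum(r.length for r in regions)
            assert span_len + inter_len == chrom_length
            # regions must not overlap gene spans
            for r in regions:
                for g in genes:
                    assert r.end <= g.start or r.start >= g.end

    def test_ownership_matches_per_base_nearest_gene(self, rng):
        for _ in range(30):
            genes, chrom_length = random_gene_fixture(rng, chrom_length=3000,
                                                      max_genes=5)
            genes = sorted(genes, key=lambda g: (g.start, g.end))
            regions = partition_intergenic(genes, chrom_length)
            _, owner = per_base_gene_labels(genes, chrom_length)
            for r in regions:
                for p in range(r.start, r.end):
                    assert owner[p] == r.assigned_gene_id, (p, r)


class TestPromoters:
    def test_plus_strand_upstream_window(self):
        p = promoter_of(gene("g", 5000, 9000, strand="+"), 20000)
        assert (p.start, p.end, p.clipped) == (4000, 5000, False)

    def test_minus_strand_reflected(self):
        p = promoter_of(gene("g", 1000, 5000, strand="-"), 20000)
        assert (p.start, p.end, p.clipped) == (5000, 6000, False)

    def test_clipped_at_chromosome_start(self):
        p = promoter_of(gene("g", 300, 900, strand="+"), 20000)
        assert (p.start, p.end, p.clipped) == (0, 300, True)

    def test_clipped_at_chromosome_end(self):
        p = promoter_of(gene("g", 100, 19500, strand="-"), 20000)
        assert (p.start, p.end, p.clipped) == (19500, 20000, True)


class TestIntronless:
    def test_counts_and_fraction(self):
        genes = [
            merge_transcripts([tx(gene_id="a", exons=((0, 100),))]),
            merge_transcripts([tx(gene_id="b", exons=((0, 50), (80, 120)))]),
            merge_transcripts([tx(gene_id="c", exons=((0, 50), (90, 130)))]),
        ]
        assert count_intronless(genes) == (1, pytest.approx(1 / 3))

    def test_empty_selection_flagged(self):
        assert count_intronless([], group="maternal") == (0, None)

    def test_planted_intronless_rate_recovered(self):
        # 1000 compact genes with a planted 10% single-exon rate: the
        # recovered fraction must sit inside the binomial 95% interval
        from imprintcons.synthetic_data import SyntheticGenomeConfig, generate

        cfg = SyntheticGenomeConfig(
            seed=11, n_genes=1000, n_chromosomes=2, chrom_length=1_600_000,
            intronless_prob=0.10, extra_exon_mean=1.0,
            intron_length_log_mean=np.log(200.0),
            intergenic_half_log_mean=np.log(300.0),
            with_repeats=False, with_tfbs=False, planted_kmer=None)
        bundle = generate(cfg)
        k, frac = count_intronless(bundle.genes.values())
        lo, hi = stats.binom.interval(0.95, 1000, 0.10)
        assert lo <= k <= hi


class TestAnnotationIO:
    def test_gtf_round_trip_preserves_models(self, tmp_path, rng):
        genes, _ = random_gene_fixture(rng, chrom_length=6000, max_genes=6)
        txs = []
        for g in genes:
            txs.append(TranscriptRecord(
                g.gene_id, g.chrom, g.strand, g.start, g.end,
                tuple(g.merged_exons),
                cds_start=g.merged_coding[0][0] if g.merged_coding else None,
                cds_end=g.merged_coding[-1][1] if g.merged_coding else None))
        path = tmp_path / "genes.gtf"
        io_mod.write_gtf(path, txs)
        models = build_gene_models(io_mod.read_gtf(path))
        assert set(models) == {g.gene_id for g in genes}
        for g in genes:
            m = models[g.gene_id]
            assert m.span == g.span
            assert m.merged_exons == list(g.merged_exons)
            assert m.strand == g.strand

    def test_bed12_reader(self, tmp_path):
        line = "chr1\t100\t600\tgeneA\t0\t+\t150\t550\t0\t2\t100,200\t0,300\n"
        path = tmp_path / "genes.bed"
        path.write_text(line)
        (rec,) = io_mod.read_bed12(path)
        assert rec.exons == ((100, 200), (400, 600))
        assert (rec.cds_start, rec.cds_end) == (150, 550)
        m = merge_transcripts([rec])
        assert m.merged_coding == [(150, 200), (400, 550)]

    def test_gene_group_file_round_trip(self, tmp_path):
        groups = {"g1": "maternal", "g2": "autosomal"}
        path = tmp_path / "groups.tsv"
        io_mod.write_gene_groups(path, groups)
        assert io_mod.read_gene_groups(path) == groups
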