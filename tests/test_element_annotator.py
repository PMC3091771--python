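"""Element classification, overlap flagging, distances, and summaries."""

from __future__ import annotations

import numpy as np
import pytest

from imprintcons.element_annotator import (
    ConservedElement,
    GenomeAnnotation,
    RepeatFeature,
    annotate_elements,
    annotate_overlaps,
    build_track_trees,
    cgi_conservation_summary,
    classify_element,
    classify_unique,
    coverage_summary,
    exon_distance_profile,
    filter_elements,
    first_repeat_category,
    gene_site_association,
    l1_summary,
    repeat_category,
    signed_exon_distance,
)
from imprintcons.genome_model import GeneModel, promoter_of

from oracles import (
    classify_element_bruteforce,
    covered_fraction_bruteforce,
    exon_distance_bruteforce,
    overlaps_bruteforce,
    per_base_gene_labels,
    random_gene_fixture,
)


def el(start, end, chrom="chr1", score=100.0):
    return ConservedElement(chrom, start, end, score)


@pytest.fixture()
def two_gene_annotation():
    # gene A: exons [100,250),[400,500); coding [150,250),[400,450)
    # gene B: single exon [700,900), coding [750,850)
    a = GeneModel("A", "chr1", "+", 100, 500, [(100, 250), (400, 500)],
                  [(150, 250), (400, 450)])
    b = GeneModel("B", "chr1", "-", 700, 900, [(700, 900)], [(750, 850)])
    return GenomeAnnotation({"A": a, "B": b}, {"chr1": 1200})


class TestFilter:
    def test_length_boundary_inclusive(self):
        els = [el(0, 19), el(30, 50), el(60, 81)]
        kept, frac = filter_elements(els)
        assert [(e.start, e.end) for e in kept] == [(30, 50), (60, 81)]
        assert frac == pytest.approx(2 / 3)

    def test_all_long_is_identity(self):
        els = [el(0, 40), el(50, 100)]
        kept, frac = filter_elements(els)
        assert kept == els and frac == 1.0

    def test_generator_short_fraction_drives_retention(self, small_bundle):
        kept, frac = filter_elements(small_bundle.elements)
        truth = small_bundle.ground_truth
        expected = 1 - truth.n_short_elements / len(small_bundle.elements)
        assert frac == pytest.approx(expected)


class TestClassification:
    def test_element_inside_intron(self, two_gene_annotation):
        e = classify_element(el(300, 340), two_gene_annotation)
        assert (e.element_class, e.assigned_gene_id) == ("intronic", "A")

    def test_element_straddling_intron_and_coding_exon(self, two_gene_annotation):
        e = classify_element(el(390, 430), two_gene_annotation)
        assert e.element_class == "coding"
        assert not e.fully_coding

    def test_fully_coding_flag(self, two_gene_annotation):
        e = classify_element(el(410, 440), two_gene_annotation)
        assert e.element_class == "coding" and e.fully_coding

    def test_utr_exon_without_coding_overlap(self, two_gene_annotation):
        e = classify_element(el(100, 140), two_gene_annotation)
        assert e.element_class == "UTR"

    def test_intergenic_halves_assign_to_nearest(self, two_gene_annotation):
        # gap [500,700) halves at 600
        left = classify_element(el(520, 560), two_gene_annotation)
        right = classify_element(el(620, 660), two_gene_annotation)
        assert (left.element_class, left.assigned_gene_id) == ("intergenic", "A")
        assert (right.element_class, right.assigned_gene_id) == ("intergenic", "B")

    def test_chromosome_without_genes_flagged(self, two_gene_annotation):
        e = classify_element(el(10, 60, chrom="chr9"), two_gene_annotation)
        assert e.element_class == "intergenic"
        assert e.assigned_gene_id is None

    def test_span_straddler_follows_genic_rule(self, two_gene_annotation):
        # overlaps gene A's span by 10 bp (intron side) and intergenic DNA
        e = classify_element(el(490, 540), two_gene_annotation)
        assert e.element_class == "UTR"  # [490,500) is exonic for A
        e2 = classify_element(el(250, 520), two_gene_annotation)
        assert e2.assigned_gene_id == "A"

    def test_matches_per_base_oracle_on_random_fixtures(self, rng):
        for _ in range(30):
            genes, chrom_length = random_gene_fixture(rng, chrom_length=4000,
                                                      max_genes=6)
            ann = GenomeAnnotation({g.gene_id: g for g in genes},
                                   {"chrT": chrom_length})
            region, owner = per_base_gene_labels(genes, chrom_length)
            for _ in range(40):
                s = int(rng.integers(0, chrom_length - 60))
                e = s + int(rng.integers(20, 60))
                got = classify_element(el(s, e, chrom="chrT"), ann)
                cls, gid = classify_element_bruteforce(s, e, genes, region, owner)
                assert (got.element_class, got.assigned_gene_id) == (cls, gid)


class TestOverlapFlags:
    def test_one_base_overlap_sets_flag(self):
        tracks = {"cpg_island": build_track_trees([("chr1", 29, 60)])}
        e = annotate_overlaps(el(10, 30), tracks)
        assert e.overlap_flags == {"cpg_island"}

    def test_half_open_adjacency_does_not_flag(self):
        tracks = {"cpg_island": build_track_trees([("chr1", 30, 60)])}
        e = annotate_overlaps(el(10, 30), tracks)
        assert e.overlap_flags == set()

    def test_matches_brute_force_on_random_tracks(self, rng):
        for _ in range(30):
            track = []
            for _ in range(8):
                s = int(rng.integers(0, 900))
                track.append(("chr1", s, s + int(rng.integers(1, 80))))
            trees = {"t": build_track_trees(track)}
            s = int(rng.integers(0, 950))
            e = s + int(rng.integers(1, 50))
            got = "t" in annotate_overlaps(el(s, e), trees).overlap_flags
            assert got == overlaps_bruteforce(s, e, [(a, b) for _, a, b in track])


class TestRepeats:
    def test_category_mapping(self):
        assert repeat_category("AluY") == "SINE_Alu"
        assert repeat_category("MIRb") == "MIR"
        assert repeat_category("L1PA3") == "L1"
        assert repeat_category("L1MA4") == "L1"
        assert repeat_category("L2a") == "L2"
        assert repeat_category("MLT1A") == "LTR"
        assert repeat_category("MER20") == "MER"
        assert repeat_category("(CA)n", "Simple_repeat") == "low_complexity_simple"
        assert repeat_category("Zaphod") == "other"

    def test_l1m_flag_from_name_prefix(self):
        assert RepeatFeature("chr1", 0, 10, "L1MA4").is_L1M
        assert not RepeatFeature("chr1", 0, 10, "L1PA3").is_L1M

    def test_first_overlapping_repeat_wins(self):
        reps = [RepeatFeature("chr1", 5, 50, "L1MA4"),
                RepeatFeature("chr1", 60, 80, "AluY")]
        trees = build_track_trees(reps)
        assert first_repeat_category(el(10, 70), trees) == "L1"

    def test_single_overlap(self):
        trees = build_track_trees([RepeatFeature("chr1", 5, 50, "MIRb")])
        assert first_repeat_category(el(10, 70), trees) == "MIR"

    def test_tie_broken_by_longer_overlap(self):
        reps = [RepeatFeature("chr1", 0, 20, "AluY"),
                RepeatFeature("chr1", 0, 40, "MIRb")]
        trees = build_track_trees(reps)
        assert first_repeat_category(el(10, 50), trees) == "MIR"

    def test_no_overlap_absent(self):
        trees = build_track_trees([RepeatFeature("chr1", 100, 120, "AluY")])
        assert first_repeat_category(el(10, 50), trees) is None


class TestUnique:
    def test_intronic_without_flags_is_unique(self, two_gene_annotation):
        e = classify_element(el(300, 340), two_gene_annotation)
        assert classify_unique(e)

    def test_repeat_overlap_breaks_uniqueness(self, two_gene_annotation):
        e = classify_element(el(520, 560), two_gene_annotation)
        e.overlap_flags.add("repeat")
        assert not classify_unique(e)

    def test_exonic_elements_never_unique(self, two_gene_annotation):
        e = classify_element(el(410, 440), two_gene_annotation)
        assert not classify_unique(e)


class TestExonDistance:
    GENE = GeneModel("g", "chr1", "+", 100, 500, [(100, 250), (400, 500)],
                     [(150, 250)])

    def test_intronic_nearest_edge(self):
        # intron [250,400): element [300,340): gaps 50 (left) and 60 (right)
        assert signed_exon_distance(el(300, 340), self.GENE) == 50

    def test_abutting_element_distance_zero(self):
        assert signed_exon_distance(el(250, 290), self.GENE) == 0

    def test_straddling_element_negative_penetration(self):
        # [390,430) penetrates 30 bp into exon [400,500)
        assert signed_exon_distance(el(390, 430), self.GENE) == -30

    def test_fully_inside_exon_uses_min_gap(self):
        assert signed_exon_distance(el(420, 460), self.GENE) == -20

    def test_matches_per_base_oracle(self, rng):
        for _ in range(30):
            genes, chrom_length = random_gene_fixture(rng, chrom_length=3000,
                                                      max_genes=3)
            for g in genes:
                for _ in range(10):
                    s = int(rng.integers(max(0, g.start - 50), g.end))
                    e = s + int(rng.integers(5, 80))
                    assert signed_exon_distance(el(s, e), g) == \
                        exon_distance_bruteforce(s, e, g)

    def test_profile_counts_sum_to_profiled_elements(self, two_gene_annotation):
        els = [el(300, 340), el(255, 280), el(410, 440), el(120, 160)]
        for e in els:
            classify_element(e, two_gene_annotation)
        prof = exon_distance_profile(els, two_gene_annotation)
        assert sum(prof.counts.values()) == prof.n_profiled == 4

    def test_planted_decay_yields_decreasing_profile(self, small_bundle, small_result):
        prof = exon_distance_profile(
            small_result.elements, small_result.annotation, bin_width=500)
        near = sum(c for b, c in prof.counts.items() if 0 <= b < 2)
        far = sum(c for b, c in prof.counts.items() if 4 <= b < 6)
        assert near > far


class TestCoverage:
    def test_hand_computed_coverage(self):
        g = GeneModel("g", "chr1", "+", 0, 10_100,
                      [(0, 50), (10_050, 10_100)], [])
        ann = GenomeAnnotation({"g": g}, {"chr1": 10_100})
        e = classify_element(el(1000, 1074), ann)
        df = coverage_summary([e], ann, "intronic")
        row = df.iloc[0]
        assert row["covered_fraction"] == pytest.approx(0.0074)
        assert row["per_10kb"] == pytest.approx(1.0)

    def test_no_elements_zero_coverage(self, two_gene_annotation):
        df = coverage_summary([], two_gene_annotation, "intergenic")
        assert (df["covered_fraction"] == 0).all()

    def test_matches_per_base_union(self, rng, two_gene_annotation):
        els = []
        for _ in range(12):
            s = int(rng.integers(250, 390))
            els.append(classify_element(el(s, s + int(rng.integers(5, 40))),
                                        two_gene_annotation))
        df = coverage_summary(els, two_gene_annotation, "intronic")
        intronic = [e.interval for e in els if e.element_class == "intronic"]
        expected = covered_fraction_bruteforce(
            [(max(s, 250), min(e, 400)) for s, e in intronic], [(250, 400)])
        got = df.set_index("gene_id").loc["A", "covered_fraction"]
        assert got == pytest.approx(expected)


class TestTrackSummaries:
    def test_cgi_fully_covered_and_uncovered(self, two_gene_annotation):
        islands = [("chr1", 300, 340), ("chr1", 600, 650)]
        e = classify_element(el(290, 350), two_gene_annotation)
        df = cgi_conservation_summary(islands, [e], two_gene_annotation)
        assert df.loc[0, "overlaps_element"]
        assert df.loc[0, "covered_fraction"] == pytest.approx(1.0)
        assert not df.loc[1, "overlaps_element"]
        assert df.loc[1, "covered_fraction"] == 0.0

    def test_l1_summary_fractions(self, two_gene_annotation):
        reps = [RepeatFeature("chr1", 520, 560, "L1MA4"),
                RepeatFeature("chr1", 620, 660, "L1PA3")]
        els = [classify_element(el(530, 555), two_gene_annotation)]
        df = l1_summary(reps, els, two_gene_annotation).set_index("group")
        assert df.loc["autosomal", "n_l1"] == 2
        assert df.loc["autosomal", "frac_l1m"] == pytest.approx(0.5)
        assert df.loc["autosomal", "frac_l1_conserved"] == pytest.approx(0.5)

    def test_site_association_and_cooccurrence(self, two_gene_annotation):
        ann = two_gene_annotation
        promoters = {gid: promoter_of(g, 1200) for gid, g in ann.genes.items()}
        tracks = {
            "yy1": [("chr1", 300, 320)],      # intron of A
            "ctcf": [("chr1", 520, 540)],     # intergenic half of A
        }
        df = gene_site_association(ann, tracks, promoters).set_index("gene_id")
        assert df.loc["A", "yy1_intronic"]
        assert df.loc["A", "ctcf_intergenic"]
        assert bool(df.loc["A", "co_occurrence"])
        assert not df.loc["B", "yy1_any"]
        assert not bool(df.loc["B", "co_occurrence"])

    def test_site_restriction_to_conserved_sites(self, two_gene_annotation):
        ann = two_gene_annotation
        tracks = {"ctcf": [("chr1", 520, 540)]}
        no_el = gene_site_association(ann, tracks, None, elements=[],
                                      require_element_overlap=True)
        assert not no_el.set_index("gene_id").loc["A", "ctcf_any"]
        cons = gene_site_association(
            ann, tracks, None,
            elements=[el(530, 560)], require_element_overlap=True)
        assert cons.set_index("gene_id").loc["A", "ctcf_any"]


class TestClassPartition:
    def test_every_retained_element_has_one_class(self, small_bundle, small_result):
        df = small_result.element_table
        assert df["element_class"].notna().all()
        assert set(df["element_class"]) <= {"coding", "UTR", "intronic", "intergenic"}
        counts = df["element_class"].value_counts()
        assert counts.sum() == len(df)

    def test_repeat_histogram_totals_match_flagged_elements(self, small_result):
        df = small_result.element_table
        hist = small_result.repeat_histogram
        assert hist["count"].sum() == int(df["overlaps_repeat"].sum())
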