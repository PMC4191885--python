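"""File dialects, the window-assignment rule and the location summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domaingrn.peaks import (
    GeneModel,
    GeneModelSet,
    Peak,
    PeakSet,
    WindowRule,
    assign_targets,
    genomic_distribution_summary,
    read_gene_models,
    read_peaks,
    write_peaks_bed,
)
from domaingrn.synthetic import SyntheticGenomeSpec, generate_toy_genome_and_peaks
from oracles import assign_targets_all_pairs

# --- readers ----------------------------------------------------------------


def test_bed12_tss_tes_conventions(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text(
        "chr1\t100\t200\tgplus\t0\t+\n"
        "chr1\t100\t200\tgminus\t0\t-\n"
    )
    genes = read_gene_models(bed, format="BED12")
    assert genes["gplus"].tss == 100 and genes["gplus"].tes == 199
    assert genes["gminus"].tss == 199 and genes["gminus"].tes == 100


def test_bed12_blocks_and_thick_region(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text(
        "chr1\t100\t1000\tg1\t0\t+\t150\t900\t0\t2\t200,300\t0,600\n"
    )
    g = read_gene_models(bed, format="BED12")["g1"]
    assert g.exons == ((100, 300), (700, 1000))
    assert g.cds == (150, 900)


def test_gtf_longest_transcript_wins(tmp_path):
    gtf = tmp_path / "genes.gtf"
    attrs_short = 'gene_id "g1"; transcript_id "g1.short";'
    attrs_long = 'gene_id "g1"; transcript_id "g1.long";'
    gtf.write_text(
        f"chr1\tsrc\ttranscript\t1001\t1500\t.\t+\t.\t{attrs_short}\n"
        f"chr1\tsrc\texon\t1001\t1500\t.\t+\t.\t{attrs_short}\n"
        f"chr1\tsrc\ttranscript\t1001\t1900\t.\t+\t.\t{attrs_long}\n"
        f"chr1\tsrc\texon\t1001\t1900\t.\t+\t.\t{attrs_long}\n"
    )
    genes = read_gene_models(gtf, format="GTF")
    assert len(genes) == 1
    assert genes["g1"].length == 900  # the 900 bp transcript wins
    assert genes["g1"].start == 1000 and genes["g1"].end == 1900


def test_unknown_strand_rejected():
    with pytest.raises(ValueError, match="strand"):
        GeneModel("g", "chr1", ".", 0, 100)


def test_macs_xls_coordinate_normalization(tmp_path):
    xls = tmp_path / "peaks.xls"
    xls.write_text(
        "# MACS comment line\n"
        "chr\tstart\tend\tlength\tsummit\ttags\t-10*log10(pvalue)\tfold_enrichment\n"
        "chr1\t101\t200\t100\t50\t30\t120.5\t9.1\n"
    )
    peaks = read_peaks(xls, format="MACS-xls")
    p = peaks.peaks[0]
    assert (p.start, p.end) == (100, 200)  # 1-based inclusive -> 0-based half-open
    assert p.summit == 150
    assert p.score == pytest.approx(120.5)


def test_bed_peak_summit_fallback_midpoint(tmp_path):
    bed = tmp_path / "peaks.bed"
    bed.write_text("chr1\t100\t201\n")
    p = read_peaks(bed, format="BED").peaks[0]
    assert p.summit == 150


def test_peak_roundtrip(tmp_path):
    peaks = PeakSet(
        [Peak("p1", "chr1", 100, 301, 173, 55.0), Peak("p2", "chr2", 0, 11, 3, 1.5)]
    )
    out = tmp_path / "peaks.bed"
    write_peaks_bed(peaks, out)
    assert read_peaks(out, format="BED") == peaks


def test_summit_outside_interval_rejected():
    with pytest.raises(ValueError, match="summit"):
        Peak("p", "chr1", 100, 200, 200)


# --- window rule ------------------------------------------------------------

PLUS = GeneModelSet([GeneModel("g", "chr1", "+", 100_000, 120_000)])
MINUS = GeneModelSet([GeneModel("g", "chr1", "-", 100_000, 120_000)])


def _assigned(genes, summit, rule=None):
    peaks = PeakSet([Peak("p", "chr1", summit - 10, summit + 11, summit)])
    return {t.gene_id for t in assign_targets(peaks, genes, rule or WindowRule())}


def test_upstream_boundary_inclusive_plus_strand():
    assert _assigned(PLUS, 90_000) == {"g"}  # exactly TSS - 10 kb: inside
    assert _assigned(PLUS, 89_999) == set()


def test_upstream_boundary_inclusive_minus_strand():
    # minus-strand TSS = 119_999; 10 kb upstream is genomic rightwards
    assert _assigned(MINUS, 129_999) == {"g"}
    assert _assigned(MINUS, 130_000) == set()


def test_downstream_extent_both_strands():
    assert _assigned(PLUS, 122_999) == {"g"}
    assert _assigned(PLUS, 123_000) == set()
    assert _assigned(MINUS, 97_000) == {"g"}
    assert _assigned(MINUS, 96_999) == set()


def test_per_gene_override_mirrors_distal_promoter_case():
    """A 17 kb-upstream summit is captured only with the gene's override."""
    rule = WindowRule(per_gene_overrides={"g": 17_491})
    summit = 100_000 - 17_000
    assert _assigned(PLUS, summit, rule) == {"g"}
    assert _assigned(PLUS, summit) == set()
    # the override boundary itself is inside
    assert _assigned(PLUS, 100_000 - 17_491, rule) == {"g"}
    assert _assigned(PLUS, 100_000 - 17_492, rule) == set()


def test_relation_and_distance_fields():
    rule = WindowRule()
    peaks = PeakSet(
        [
            Peak("up", "chr1", 94_950, 95_051, 95_000),
            Peak("body", "chr1", 109_950, 110_051, 110_000),
            Peak("down", "chr1", 120_950, 121_051, 121_000),
        ]
    )
    rel = {t.peak_id: (t.relation, t.distance_to_tss) for t in assign_targets(peaks, PLUS, rule)}
    assert rel == {
        "up": ("upstream-promoter", -5_000),
        "body": ("gene-body", 10_000),
        "down": ("downstream", 21_000),
    }


def test_any_overlap_anchor_is_more_permissive():
    rule = WindowRule(anchor="any-overlap")
    peaks = PeakSet([Peak("p", "chr1", 89_500, 90_200, 89_600)])  # summit outside
    assert {t.gene_id for t in assign_targets(peaks, PLUS, rule)} == {"g"}
    assert assign_targets(peaks, PLUS, WindowRule()) == []


def test_multi_gene_hits_all_reported():
    genes = GeneModelSet(
        [
            GeneModel("g1", "chr1", "+", 100_000, 120_000),
            GeneModel("g2", "chr1", "-", 121_000, 140_000),
        ]
    )
    # summit downstream of g1 (+) and upstream of g2 (-): inside both windows
    assert _assigned(genes, 122_000) == {"g1", "g2"}


@settings(max_examples=25)
@given(shift=st.integers(min_value=0, max_value=10**6))
def test_assignment_translation_invariant(shift):
    spec = SyntheticGenomeSpec(seed=6, n_genes=6, n_peaks=30, frac_in_window=0.5,
                               chrom_length=1_000_000, n_chroms=1)
    genes, peaks, _, _ = generate_toy_genome_and_peaks(spec)
    rule = WindowRule()
    base = {(t.peak_id, t.gene_id) for t in assign_targets(peaks, genes, rule)}
    genes2 = GeneModelSet(
        GeneModel(g.gene_id, g.chrom, g.strand, g.start + shift, g.end + shift)
        for g in genes
    )
    peaks2 = PeakSet(
        Peak(p.peak_id, p.chrom, p.start + shift, p.end + shift, p.summit + shift)
        for p in peaks
    )
    shifted = {(t.peak_id, t.gene_id) for t in assign_targets(peaks2, genes2, rule)}
    assert shifted == base


def test_assignment_matches_all_pairs_oracle():
    rule = WindowRule(per_gene_overrides={"g0007": 17_491})
    spec = SyntheticGenomeSpec(seed=13, n_genes=40, n_peaks=300, frac_in_window=0.6,
                               n_chroms=2, chrom_length=3_000_000)
    genes, peaks, _, _ = generate_toy_genome_and_peaks(spec, rule)
    got = {(t.peak_id, t.gene_id) for t in assign_targets(peaks, genes, rule)}
    assert got == assign_targets_all_pairs(peaks, genes, rule)


# --- location summary -------------------------------------------------------


def test_single_peak_in_intron(toy_genes, single_peak_set):
    # plus-strand gene: intron spans [101_000, 110_000)
    summary = genomic_distribution_summary(single_peak_set("chr1", 105_000), toy_genes)
    assert summary.percentages["intron"] == 100.0


def test_far_peaks_are_intergenic(toy_genes, single_peak_set):
    summary = genomic_distribution_summary(single_peak_set("chr1", 900_000), toy_genes)
    assert summary.percentages["intergenic"] == 100.0


def test_utr_orientation_follows_strand(toy_genes, single_peak_set):
    # plus gene: exon bases before CDS start (100_500) are 5'UTR
    s = genomic_distribution_summary(single_peak_set("chr1", 100_200), toy_genes)
    assert s.percentages["5utr"] == 100.0
    # minus gene: exon bases right of CDS end (319_500) are 5'UTR in gene orientation
    s = genomic_distribution_summary(single_peak_set("chr1", 319_800), toy_genes)
    assert s.percentages["5utr"] == 100.0
    # minus gene: exon bases left of CDS start are 3'UTR
    s = genomic_distribution_summary(single_peak_set("chr1", 303_000), toy_genes)
    assert s.percentages["3utr"] == 100.0


def test_hand_classified_ten_peak_fixture(toy_genes):
    placements = [
        ("chr1", 100_200, "5utr"),        # + gene, exon before CDS
        ("chr1", 100_700, "exon"),        # + gene, coding exon
        ("chr1", 105_000, "intron"),
        ("chr1", 117_000, "3utr"),        # + gene, exon past CDS end
        ("chr1", 303_000, "3utr"),        # - gene, exon before CDS start
        ("chr1", 99_500, "upstream_0_1000bp"),    # 500 bp upstream of + TSS
        ("chr1", 98_000, "upstream_1000_3000bp"),
        ("chr1", 91_000, "upstream_3000_10000bp"),
        ("chr1", 700_000, "intergenic"),
        ("chr1", 322_000, "upstream_1000_3000bp"),  # 2 kb upstream of - TSS (319_999)
    ]
    peaks = PeakSet(
        [
            Peak(f"p{i}", chrom, pos - 10, pos + 11, pos)
            for i, (chrom, pos, _) in enumerate(placements)
        ]
    )
    summary = genomic_distribution_summary(peaks, toy_genes)
    expected = {}
    for _, _, cat in placements:
        expected[cat] = expected.get(cat, 0) + 10.0
    for cat, pct in expected.items():
        assert summary.percentages[cat] == pytest.approx(pct)
    assert sum(summary.percentages.values()) == pytest.approx(100.0, abs=1e-9)
    cum = list(summary.cumulative_upstream.values())
    assert cum == sorted(cum)
    assert summary.cumulative_upstream[10000] == pytest.approx(40.0)


def test_percentages_sum_to_100_on_synthetic_fixture():
    spec = SyntheticGenomeSpec(seed=3, n_genes=30, n_peaks=200, frac_in_window=0.7)
    genes, peaks, _, _ = generate_toy_genome_and_peaks(spec)
    summary = genomic_distribution_summary(peaks, genes)
    assert sum(summary.percentages.values()) == pytest.approx(100.0, abs=1e-9)
    cum = list(summary.cumulative_upstream.values())
    assert cum == sorted(cum)
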