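"""Feature classification, nearest-TSS distances, and distributions."""

import numpy as np
import pytest

from cistrome.annotate import (
    CATEGORIES,
    FeatureAnnotation,
    GeneModel,
    classify_peak_location,
    distance_distribution,
    feature_distribution,
    nearest_tss,
    read_gtf,
    write_gtf,
)
from cistrome.intervals_io import GenomicInterval, Peak


def make_peak(anchor, chrom="chr1", half=50, name="p"):
    return Peak(
        GenomicInterval(chrom, anchor - half, anchor + half, name), half
    )


def oracle_classify(anchor, genes, pw=10_000, dw=10_000):
    """Brute-force per-gene window scan with the documented precedence."""
    cats = set()
    for g in genes:
        up = (g.tss - anchor) if g.strand == "+" else (anchor - g.tss)
        if 0 <= up <= pw:
            cats.add("promoter")
        if g.tx_start <= anchor < g.tx_end:
            cats.add(
                "exon" if any(s <= anchor < e for s, e in g.exons) else "intron"
            )
        past = (anchor - g.tts) if g.strand == "+" else (g.tts - anchor)
        if 1 <= past <= dw:
            cats.add("downstream")
    for c in ("promoter", "exon", "intron", "downstream"):
        if c in cats:
            return c
    return "intergenic"


def random_genes(rng, n, chrom="chr1", span=1_000_000):
    genes = []
    pos = 1000
    for i in range(n):
        pos += int(rng.integers(5_000, span // n))
        length = int(rng.integers(2_000, 20_000))
        k = int(rng.integers(1, 5))
        cuts = np.sort(rng.choice(length + 1, size=2 * k, replace=False))
        exons = tuple(
            (pos + int(cuts[2 * e]), pos + int(cuts[2 * e + 1]))
            for e in range(k)
            if cuts[2 * e] < cuts[2 * e + 1]
        ) or ((pos, pos + length),)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i:02d}", chrom, strand, pos, pos + length, exons))
        pos += length
    return genes


PLUS_GENE = GeneModel("gA", "chr1", "+", 50_000, 60_000, ((50_000, 60_000),))
MINUS_GENE = GeneModel("gB", "chr1", "-", 10_000, 20_000, ((10_000, 20_000),))


class TestClassification:
    @pytest.mark.parametrize(
        "anchor, expected",
        [
            (41_000, "promoter"),     # 9 kb upstream of the TSS
            (40_000, "promoter"),     # exactly 10 kb upstream (inclusive)
            (39_999, "intergenic"),   # 10,001 bp upstream, outside the window
            (55_000, "exon"),         # inside the single-exon body
            (65_000, "downstream"),   # 5 kb past the TTS
            (70_001, "intergenic"),   # 10,002 bp past the TTS
        ],
    )
    def test_plus_strand_windows(self, anchor, expected):
        ann = classify_peak_location(make_peak(anchor), [PLUS_GENE])
        assert ann.category == expected

    def test_intron_between_exons(self):
        gene = GeneModel(
            "g", "chr1", "+", 1000, 9000, ((1000, 2000), (8000, 9000))
        )
        assert classify_peak_location(make_peak(5000), [gene]).category == "intron"

    def test_unknown_chromosome_is_intergenic(self):
        ann = classify_peak_location(
            make_peak(5000, chrom="chrUn"), [PLUS_GENE]
        )
        assert ann.category == "intergenic"
        assert ann.assigned_gene is None

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        genes = random_genes(rng, 10)
        for _ in range(100):
            anchor = int(rng.integers(1000, 1_000_000))
            ann = classify_peak_location(make_peak(anchor), genes)
            assert ann.category == oracle_classify(anchor, genes)

    def test_categories_partition_any_peak_set(self, default_pipeline):
        table = default_pipeline.feature_table
        assert table["count"].sum() == len(default_pipeline.common_peaks)
        assert table["fraction"].sum() == pytest.approx(1.0)


class TestNearestTss:
    def test_minus_strand_sign_convention(self):
        # tss of the '-' gene is 19999; anchor 1 kb beyond it is upstream
        gene_id, dist, _ = nearest_tss(make_peak(20_999), [MINUS_GENE])
        assert (gene_id, dist) == ("gB", -1000)

    def test_anchor_at_tss_is_zero(self):
        _, dist, _ = nearest_tss(make_peak(50_000, half=10), [PLUS_GENE])
        assert dist == 0

    def test_sign_flips_when_strand_mirrors_at_same_tss(self):
        plus = GeneModel("gp", "chr1", "+", 30_000, 40_000, ((30_000, 40_000),))
        minus = GeneModel("gm", "chr1", "-", 20_001, 30_001, ((20_001, 30_001),))
        assert plus.tss == minus.tss == 30_000
        _, d_plus, _ = nearest_tss(make_peak(32_000), [plus])
        _, d_minus, _ = nearest_tss(make_peak(32_000), [minus])
        assert d_plus == -d_minus == 2000

    def test_tie_breaks_lexicographically_and_flags(self):
        g1 = GeneModel("gA", "chr1", "+", 1000, 2000, ((1000, 2000),))
        g2 = GeneModel("gB", "chr1", "+", 3000, 4000, ((3000, 4000),))
        gene_id, _, tie = nearest_tss(make_peak(2000), [g2, g1])
        assert gene_id == "gA"
        assert tie

    def test_translation_invariance_and_oracle(self):
        rng = np.random.default_rng(5)
        genes = random_genes(rng, 20)
        shift = 37_000
        shifted = [
            GeneModel(
                g.gene_id, g.chrom, g.strand, g.tx_start + shift,
                g.tx_end + shift,
                tuple((s + shift, e + shift) for s, e in g.exons),
            )
            for g in genes
        ]
        for _ in range(200):
            anchor = int(rng.integers(1000, 1_000_000))
            gene_id, dist, _ = nearest_tss(make_peak(anchor), genes)
            # brute-force oracle
            best = min(genes, key=lambda g: (abs(anchor - g.tss), g.gene_id))
            sign = 1 if best.strand == "+" else -1
            assert gene_id == best.gene_id
            assert dist == (anchor - best.tss) * sign
            # translation invariance
            gene_id2, dist2, _ = nearest_tss(make_peak(anchor + shift), shifted)
            assert (gene_id2, dist2) == (gene_id, dist)


class TestDistributions:
    def test_within_50kb_boundary_is_closed(self):
        anns = [
            FeatureAnnotation(f"p{i}", "intergenic", "g", d)
            for i, d in enumerate([0, 49_999, 50_000, 120_000])
        ]
        table, n_un = distance_distribution(anns, [50_000])
        assert n_un == 0
        assert table.iloc[0]["count"] == 3
        assert table.iloc[0]["fraction"] == pytest.approx(0.75)

    def test_empty_input_gives_empty_table(self):
        table, n_un = distance_distribution([], [50_000])
        assert len(table) == 0 and n_un == 0

    def test_histogram_matches_direct_tally(self):
        rng = np.random.default_rng(9)
        dists = np.concatenate([
            rng.integers(0, 30_000, 600),
            rng.integers(30_000, 500_000, 400),
        ])
        anns = [
            FeatureAnnotation(f"p{i}", "intergenic", "g", int(d))
            for i, d in enumerate(dists)
        ]
        breaks = [10_000, 50_000, 100_000]
        table, _ = distance_distribution(anns, breaks)
        edges = [0] + breaks + [np.inf]
        for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
            expected = int(np.sum((dists > lo) & (dists <= hi))) if lo else int(
                np.sum(dists <= hi)
            )
            assert table.iloc[i]["count"] == expected
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_unassigned_reported_separately(self):
        anns = [
            FeatureAnnotation("p0", "intergenic", None, None),
            FeatureAnnotation("p1", "promoter", "g", 100),
        ]
        table, n_un = distance_distribution(anns, [1000])
        assert n_un == 1
        assert table["count"].sum() == 1

    def test_feature_fractions(self):
        anns = (
            [FeatureAnnotation(f"a{i}", "promoter", "g", 0) for i in range(1)]
            + [FeatureAnnotation(f"b{i}", "intron", "g", 0) for i in range(4)]
            + [FeatureAnnotation(f"c{i}", "intergenic", "g", 0) for i in range(5)]
        )
        table = feature_distribution(anns).set_index("category")
        assert table.loc["promoter", "fraction"] == pytest.approx(0.1)
        assert table.loc["intron", "fraction"] == pytest.approx(0.4)
        assert table.loc["intergenic", "fraction"] == pytest.approx(0.5)
        assert list(table.index) == list(CATEGORIES)


class TestGtfRoundTrip:
    def test_write_then_read_preserves_gene_models(self, tmp_path, default_sim):
        path = tmp_path / "genes.gtf"
        write_gtf(default_sim.genes, path)
        back = read_gtf(path)
        assert back == sorted(default_sim.genes, key=lambda g: g.gene_id)
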