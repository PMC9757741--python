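import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitecoopt.core_genomics import ChromSizes, CoverageTrack, GeneModel, GenomicInterval
from mitecoopt.promoters import (
    annotate_promoters,
    directional_signal_test,
    link_site_to_first_exon,
)

SIZES = ChromSizes({"chrI": 20_000})


def make_track(stranded=True, sizes=SIZES):
    return CoverageTrack(sizes, stranded=stranded)


def plus_gene(gene_id="g1", tss=10_000, exon_offset=500, exon_len=200, body_len=3000):
    return GeneModel(
        gene_id,
        "chrI",
        "+",
        tss,
        GenomicInterval("chrI", tss + exon_offset, tss + exon_offset + exon_len, "+"),
        GenomicInterval("chrI", tss, tss + body_len, "+"),
    )


def minus_gene(gene_id="g2", tss=10_000, exon_offset=500, exon_len=200, body_len=3000):
    return GeneModel(
        gene_id,
        "chrI",
        "-",
        tss,
        GenomicInterval("chrI", tss - exon_offset - exon_len + 1, tss - exon_offset + 1, "-"),
        GenomicInterval("chrI", tss - body_len + 1, tss + 1, "-"),
    )


SITE = GenomicInterval("chrI", 9_800, 10_000)  # midpoint 9900


class TestLinking:
    def test_continuous_coverage_links(self):
        rna = make_track()
        gene = plus_gene()
        rna.get("chrI", "+")[9_900 : gene.first_exon.end] = 3.0
        res = link_site_to_first_exon(SITE, rna, gene)
        assert res.reached and res.max_gap == 0
        assert res.path_length == gene.first_exon.start - 9_900

    def test_gap_of_exactly_200_links(self):
        rna = make_track()
        gene = plus_gene()
        rna.get("chrI", "+")[9_900 : gene.first_exon.end] = 3.0
        rna.get("chrI", "+")[10_000 : 10_200] = 0.0
        res = link_site_to_first_exon(SITE, rna, gene)
        assert res.reached and res.max_gap == 200

    def test_gap_of_201_breaks_link(self):
        rna = make_track()
        gene = plus_gene()
        rna.get("chrI", "+")[9_900 : gene.first_exon.end] = 3.0
        rna.get("chrI", "+")[10_000 : 10_201] = 0.0
        res = link_site_to_first_exon(SITE, rna, gene)
        assert not res.reached and res.max_gap == 201

    def test_midpoint_inside_exon_links_trivially(self):
        rna = make_track()
        gene = plus_gene(tss=9_500)  # exon 10000..10200 contains midpoint 9900? no
        gene = plus_gene(tss=9_300)  # exon 9800..10000
        res = link_site_to_first_exon(SITE, rna, gene)
        assert res.reached and res.trivial and res.path_length == 0

    def test_site_past_exon_never_links(self):
        rna = make_track()
        gene = plus_gene(tss=5_000)  # exon 5500..5700, midpoint 9900 beyond
        rna.get("chrI", "+")[:] = 5.0
        assert not link_site_to_first_exon(SITE, rna, gene).reached

    def test_minus_strand_gene_links_leftward(self):
        rna = make_track()
        gene = minus_gene(tss=10_050)  # exon ends at 9551, site mid 9900 upstream
        rna.get("chrI", "-")[gene.first_exon.start : 9_901] = 2.0
        res = link_site_to_first_exon(SITE, rna, gene)
        assert res.reached

    def test_matches_position_scan_oracle_on_random_tracks(self, rng):
        gene = plus_gene()
        for _ in range(50):
            rna = make_track()
            cov = rna.get("chrI", "+")
            cov[9_900 : gene.first_exon.start] = rng.integers(0, 2, 600).astype(float)
            res = link_site_to_first_exon(SITE, rna, gene, max_gap=37)
            # independent linear scan
            run, worst = 0, 0
            for v in cov[9_900 : gene.first_exon.start]:
                run = run + 1 if v == 0 else 0
                worst = max(worst, run)
            assert res.reached == (worst <= 37)
            assert res.max_gap == worst

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_adding_coverage_never_unlinks(self, data):
        gene = plus_gene()
        rna = make_track()
        cov = rna.get("chrI", "+")
        pattern = data.draw(
            st.lists(st.booleans(), min_size=600, max_size=600)
        )
        cov[9_900 : gene.first_exon.start] = np.array(pattern, dtype=float)
        before = link_site_to_first_exon(SITE, rna, gene)
        extra_pos = data.draw(st.integers(9_900, gene.first_exon.start - 1))
        cov[extra_pos] += 1.0
        after = link_site_to_first_exon(SITE, rna, gene)
        if before.reached:
            assert after.reached


class TestDirectionalTest:
    def test_downstream_only_signal_passes(self):
        rna = make_track()
        rna.get("chrI", "+")[9_975 : 10_250] = 4.0  # +75..+350 from mid 9900
        res = directional_signal_test(SITE, "+", rna)
        assert res.passed and res.pvalue < 0.05

    def test_symmetric_signal_fails(self):
        rna = make_track()
        rna.get("chrI", "+")[9_550 : 10_251] = 4.0
        res = directional_signal_test(SITE, "+", rna)
        assert not res.passed

    def test_no_signal_fails_without_error(self):
        res = directional_signal_test(SITE, "+", make_track())
        assert not res.passed

    def test_window_off_chromosome_sets_truncation_flag(self):
        site = GenomicInterval("chrI", 0, 200)
        res = directional_signal_test(site, "+", make_track())
        assert res.truncated and not res.passed

    def test_minus_strand_downstream_is_leftward(self):
        rna = make_track()
        rna.get("chrI", "-")[9_550 : 9_826] = 4.0  # -350..-75 from mid
        assert directional_signal_test(SITE, "-", rna).passed
        assert not directional_signal_test(SITE, "+", rna).passed


class TestAnnotate:
    def test_site_with_no_gene_is_not_promoter(self):
        calls = annotate_promoters([SITE], make_track(), [plus_gene(tss=18_000)])
        assert all(not c.is_promoter for c in calls)

    def test_bidirectional_promoter_yields_two_calls(self):
        # divergent pair sharing one site: '-' gene leftward, '+' gene rightward
        left = minus_gene("gl", tss=9_840)
        right = plus_gene("gr", tss=9_960)
        rna = make_track()
        rna.get("chrI", "+")[9_900 : right.first_exon.end] = 5.0
        rna.get("chrI", "-")[left.first_exon.start : 9_901] = 5.0
        calls = annotate_promoters([SITE], rna, [left, right])
        promoted = {c.gene_id for c in calls if c.is_promoter}
        assert promoted == {"gl", "gr"}

    def test_translation_invariance(self):
        offset = 1234
        gene = plus_gene()
        rna = make_track()
        rna.get("chrI", "+")[9_900 : gene.first_exon.end] = 5.0
        base = annotate_promoters([SITE], rna, [gene])

        big = ChromSizes({"chrI": 20_000 + offset})
        rna2 = CoverageTrack(big, stranded=True)
        rna2.get("chrI", "+")[offset:] = rna.get("chrI", "+")
        gene2 = GeneModel(
            "g1", "chrI", "+", gene.tss + offset,
            gene.first_exon.shift(offset), gene.body.shift(offset),
        )
        shifted = annotate_promoters([SITE.shift(offset)], rna2, [gene2])
        assert [(c.gene_id, c.is_promoter, c.path_length) for c in base] == [
            (c.gene_id, c.is_promoter, c.path_length) for c in shifted
        ]

    def test_chromosome_renaming_invariance(self):
        gene = plus_gene()
        rna = make_track()
        rna.get("chrI", "+")[9_900 : gene.first_exon.end] = 5.0
        base = annotate_promoters([SITE], rna, [gene])

        sizes = ChromSizes({"scaffold_7": 20_000})
        rna2 = CoverageTrack(sizes, stranded=True)
        rna2.data["scaffold_7"] = rna.data["chrI"]
        gene2 = GeneModel(
            "g1", "scaffold_7", "+", gene.tss,
            GenomicInterval("scaffold_7", gene.first_exon.start, gene.first_exon.end, "+"),
            GenomicInterval("scaffold_7", gene.body.start, gene.body.end, "+"),
        )
        site2 = GenomicInterval("scaffold_7", SITE.start, SITE.end)
        renamed = annotate_promoters([site2], rna2, [gene2])
        assert [(c.is_promoter, c.path_length) for c in base] == [
            (c.is_promoter, c.path_length) for c in renamed
        ]

    def test_tiny_world_truth_recovery(self, tiny_world, tiny_results):
        _, _, truth = tiny_world
        for res, species in zip(tiny_results, ("spA", "spB")):
            predicted = {
                (c.site.chrom, c.site.start, c.site.end, c.gene_id)
                for c in res.promoter_calls
                if c.is_promoter
            }
            expected = {
                (r.chrom, int(r.start), int(r.end), g)
                for r in truth.sites.query(f"species=='{species}'").itertuples()
                if r.is_promoter
                for g in r.gene_ids.split(",")
            }
            assert predicted == expected  # precision = recall = 1.0
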