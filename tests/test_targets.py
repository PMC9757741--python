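import pytest

from mitecoopt.core_genomics import GenomicInterval
from mitecoopt.promoters import PromoterCall
from mitecoopt.targets import (
    DERecord,
    call_direct_targets,
    fisher_direction_test,
    peak_promoter_overlap_fraction,
    summarize_fractions,
)


def promoter(gene_id, start, coopted=False, germline=True, chrom="chrI"):
    return PromoterCall(
        site=GenomicInterval(chrom, start, start + 200),
        gene_id=gene_id,
        gene_strand="+",
        linked=True,
        path_length=100,
        max_gap=0,
        statistic=1.0,
        pvalue=1e-6,
        directional_pass=True,
        is_promoter=True,
        is_germline_specific=germline,
        is_coopted=coopted,
    )


class TestCallDirectTargets:
    def test_down_gene_with_peak_is_direct_target(self):
        de = [DERecord("g1", -3.0, 1e-6)]
        proms = [promoter("g1", 1000, coopted=True)]
        peaks = [GenomicInterval("chrI", 1100, 1150)]
        (call,) = call_direct_targets(de, peaks, proms)
        assert call.is_direct_target and call.has_coopted_promoter

    def test_down_gene_without_peak_is_not(self):
        de = [DERecord("g1", -3.0, 1e-6)]
        (call,) = call_direct_targets(de, [], [promoter("g1", 1000)])
        assert not call.is_direct_target

    def test_up_gene_admitted_only_in_misregulated_mode(self):
        de = [DERecord("g1", 2.0, 1e-6)]
        proms = [promoter("g1", 1000)]
        peaks = [GenomicInterval("chrI", 1000, 1200)]
        (down,) = call_direct_targets(de, peaks, proms, mode="down_only")
        (mis,) = call_direct_targets(de, peaks, proms, mode="misregulated")
        assert not down.is_direct_target and mis.is_direct_target

    def test_nonsignificant_gene_never_direct(self):
        de = [DERecord("g1", -3.0, 0.01)]  # padj above the 0.001 threshold
        peaks = [GenomicInterval("chrI", 1000, 1200)]
        (call,) = call_direct_targets(de, peaks, [promoter("g1", 1000)])
        assert call.direction == "ns" and not call.is_direct_target

    def test_duplicate_gene_ids_raise(self):
        de = [DERecord("g1", -3.0, 1e-6), DERecord("g1", 1.0, 1e-6)]
        with pytest.raises(ValueError, match="g1"):
            call_direct_targets(de, [], [])

    def test_direct_targets_subset_of_down_in_default_mode(self, tiny_world, tiny_results):
        from mitecoopt import pipeline

        out, _, truth = tiny_world
        res_a, _ = tiny_results
        calls = pipeline.run_targets(out, res_a)
        assert all(c.direction == "down" for c in calls if c.is_direct_target)
        mis = pipeline.run_targets(out, res_a, mode="misregulated")
        down_set = {c.gene_id for c in calls if c.is_direct_target}
        mis_set = {c.gene_id for c in mis if c.is_direct_target}
        assert down_set <= mis_set

    def test_tiny_world_truth_recovery(self, tiny_world, tiny_results):
        from mitecoopt import pipeline

        out, _, truth = tiny_world
        res_a, _ = tiny_results
        calls = pipeline.run_targets(out, res_a)
        predicted = {c.gene_id for c in calls if c.is_direct_target}
        expected = set(
            truth.genes.query("species=='spA' and is_direct_target").gene_id
        )
        assert predicted == expected


def build_ratio_tables(n_direct=304, n_direct_coopted=193,
                       n_gs=782, n_gs_coopted=284, n_sole=171):
    """Construct call/promoter tables realizing the given counts."""
    from mitecoopt.targets import DirectTargetCall

    calls = [
        DirectTargetCall(f"t{i:04d}", "down", True, True, i < n_direct_coopted)
        for i in range(n_direct)
    ]
    promoters = []
    for i in range(n_gs):
        coopted = i < n_gs_coopted
        promoters.append(promoter(f"g{i:04d}", 1000 + 1000 * i, coopted=coopted))
    # co-opted promoters beyond n_sole get a second (non-GS) promoter
    extra = 0
    for i in range(n_sole, n_gs_coopted):
        extra += 1
        promoters.append(
            promoter(f"g{i:04d}", 900_000 + 1000 * extra, coopted=False, germline=False)
        )
    return calls, promoters


class TestSummarizeFractions:
    def test_printed_count_ratios(self):
        calls, promoters_ = build_ratio_tables()
        table = summarize_fractions(calls, promoters_).set_index("metric")
        assert table.loc["direct_targets_with_coopted_promoter", "percent"] == 63.4
        assert table.loc["germline_specific_promoters_with_pair", "percent"] == 36.3
        assert table.loc["coopted_promoters_sole_for_gene", "percent_int"] == 60

    def test_zero_numerator(self):
        calls, promoters_ = build_ratio_tables(n_direct=10, n_direct_coopted=0)
        table = summarize_fractions(calls, promoters_).set_index("metric")
        assert table.loc["direct_targets_with_coopted_promoter", "percent"] == 0.0

    def test_percentages_self_consistent(self):
        calls, promoters_ = build_ratio_tables()
        table = summarize_fractions(calls, promoters_)
        for r in table.itertuples():
            assert r.percent == int(1000.0 * r.count / r.total) / 10.0
            assert abs(r.percent - 100.0 * r.count / r.total) < 0.1

    def test_empty_calls_raise(self):
        with pytest.raises(ValueError):
            summarize_fractions([], [])


class TestPeakPromoterOverlap:
    def test_full_coverage_is_one(self):
        proms = [GenomicInterval("chrI", i * 100, i * 100 + 50) for i in range(10)]
        assert peak_promoter_overlap_fraction([GenomicInterval("chrI", 0, 5000)], proms) == 1.0

    def test_no_peaks_is_zero(self):
        proms = [GenomicInterval("chrI", 0, 50)]
        assert peak_promoter_overlap_fraction([], proms) == 0.0

    def test_empty_promoters_raise(self):
        with pytest.raises(ValueError):
            peak_promoter_overlap_fraction([GenomicInterval("chrI", 0, 50)], [])

    def test_matches_brute_force_oracle(self, rng):
        from mitecoopt.core_genomics import overlaps

        for _ in range(5):
            peaks = [
                GenomicInterval("chrI", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 5000, 100), rng.integers(1, 100, 100))
            ]
            proms = [
                GenomicInterval("chrI", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 5000, 100), rng.integers(1, 100, 100))
            ]
            brute = sum(any(overlaps(p, k) for k in peaks) for p in proms) / len(proms)
            assert peak_promoter_overlap_fraction(peaks, proms) == brute


def test_fisher_direction_test_detects_down_skew():
    de = [DERecord(f"d{i}", -2.0, 1e-6) for i in range(40)]
    de += [DERecord(f"u{i}", 2.0, 1e-6) for i in range(40)]
    bound = {f"d{i}" for i in range(30)} | {"u0"}
    odds, p = fisher_direction_test(de, bound)
    assert odds > 1 and p < 1e-6
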