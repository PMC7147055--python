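"""CNVR merging, outlier removal, singleton filter and consensus intersection."""

import numpy as np
import pytest

from afrocnv.consensus import (
    CnvRegion,
    classify_region,
    consensus_intersect,
    detect_outlier_samples,
    filter_singletons,
    merge_calls_to_cnvr,
    region_summary,
    run_consensus,
)
from afrocnv.core_io import CnvCall, GenomicInterval, ValidationError


def call(sample, start, end, cn, chrom="chr1", caller="A"):
    return CnvCall(sample, GenomicInterval(chrom, start, end), cn, float(cn), caller)


class TestMerge:
    def test_overlapping_calls_merge_to_one_region(self):
        regions = merge_calls_to_cnvr([call("S1", 100, 200, 1), call("S2", 150, 300, 3)])
        assert len(regions) == 1
        r = regions[0]
        assert (r.region.start, r.region.end) == (100, 300)
        assert r.region_class == "mixed"
        assert r.carrier_count == 2

    def test_disjoint_calls_stay_distinct(self):
        regions = merge_calls_to_cnvr([call("S1", 0, 100, 1), call("S1", 200, 300, 1)])
        assert len(regions) == 2

    def test_longest_call_wins_within_region(self):
        regions = merge_calls_to_cnvr(
            [call("S1", 100, 200, 1), call("S1", 150, 400, 3)]
        )
        assert regions[0].copy_of("S1") == 3

    def test_absent_sample_is_reference(self):
        regions = merge_calls_to_cnvr([call("S1", 0, 10, 1)])
        assert regions[0].copy_of("S9") == 2

    def test_matches_per_base_connected_components_oracle(self):
        rng = np.random.default_rng(7)
        calls = []
        for i in range(500):
            s = int(rng.integers(0, 990_000))
            calls.append(call(f"S{rng.integers(0, 30)}", s,
                              s + int(rng.integers(1, 8000)),
                              int(rng.choice([0, 1, 3, 4]))))
        regions = merge_calls_to_cnvr(calls)
        # oracle: per-base coverage, connected runs of covered bases
        cov = np.zeros(1_000_000, dtype=bool)
        for c in calls:
            cov[c.region.start:c.region.end] = True
        runs = []
        inside = False
        for idx in range(len(cov) + 1):
            v = cov[idx] if idx < len(cov) else False
            if v and not inside:
                inside, run_start = True, idx
            elif not v and inside:
                inside = False
                runs.append((run_start, idx))
        got = [(r.region.start, r.region.end) for r in regions]
        assert got == runs

    def test_region_set_invariant_to_call_order(self):
        rng = np.random.default_rng(1)
        calls = [call(f"S{i % 5}", int(rng.integers(0, 50_000)),
                      int(rng.integers(0, 50_000)) + 60_000, 1) for i in range(50)]
        a = merge_calls_to_cnvr(calls)
        b = merge_calls_to_cnvr(calls[::-1])
        assert [(r.region, sorted(r.copy_state.items())) for r in a] == \
               [(r.region, sorted(r.copy_state.items())) for r in b]


class TestClassify:
    @pytest.mark.parametrize(
        "copies,expected",
        [
            ([1, 1, 2, 2], "deletion_only"),
            ([3, 4], "insertion_only"),
            ([1, 3], "mixed"),
            ([0, 2, 2], "deletion_only"),
        ],
    )
    def test_classes(self, copies, expected):
        assert classify_region(copies) == expected

    def test_all_reference_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_region([2, 2])


class TestOutliers:
    def test_equal_counts_no_outliers(self):
        calls = [call(f"S{i}", j * 100, j * 100 + 50, 1)
                 for i in range(12) for j in range(5)]
        outliers, report = detect_outlier_samples(calls)
        assert outliers == []

    def test_extreme_sample_flagged(self):
        calls = []
        for i in range(60):
            n = 100 if i == 0 else 10
            calls += [call(f"S{i:02d}", j * 1000, j * 1000 + 50, 1) for j in range(n)]
        outliers, report = detect_outlier_samples(calls)
        assert outliers == ["S00"]
        assert report["mean_flagged"] > report["mean_retained"]

    def test_too_few_samples_refused(self):
        calls = [call(f"S{i}", 0, 10, 1) for i in range(5)]
        with pytest.raises(ValidationError, match="10 samples"):
            detect_outlier_samples(calls)

    @pytest.mark.parametrize("seed", [15, 16, 17])
    def test_synthetic_outliers_recovered(self, seed):
        from afrocnv.synthetic_cohort import CohortConfig, generate

        co = generate(CohortConfig(
            seed=seed, chromosomes=("chr1",), chrom_length=4_000_000,
            n_per_population=12, n_true_cnvrs=100, n_known_decoys=5,
        ))
        outliers, report = detect_outlier_samples(co.calls_a + co.calls_b)
        assert outliers == co.outlier_samples
        assert report["mean_flagged"] > 3 * report["mean_retained"]


class TestSingletonsAndIntersect:
    def test_singleton_filter(self):
        r1 = CnvRegion("a", GenomicInterval("chr1", 0, 10), {"S1": 1})
        r2 = CnvRegion("b", GenomicInterval("chr1", 20, 30), {"S1": 1, "S2": 3})
        assert filter_singletons([r1, r2]) == [r2]

    def test_minimum_one_bp_rule(self):
        a = [CnvRegion("a", GenomicInterval("chr1", 0, 10), {"S1": 1, "S2": 1})]
        b_hit = [CnvRegion("b", GenomicInterval("chr1", 9, 20), {"S1": 1, "S2": 1})]
        b_miss = [CnvRegion("b", GenomicInterval("chr1", 10, 20), {"S1": 1, "S2": 1})]
        assert consensus_intersect(a, b_hit) == a
        assert consensus_intersect(a, b_miss) == []

    def test_intersect_matches_brute_force(self):
        rng = np.random.default_rng(5)

        def random_regions(n, tag):
            out = []
            for i in range(n):
                s = int(rng.integers(0, 500_000))
                out.append(CnvRegion(f"{tag}{i}",
                                     GenomicInterval("chr1", s, s + int(rng.integers(1, 20_000))),
                                     {"S1": 1, "S2": 1}))
            return out

        a, b = random_regions(80, "a"), random_regions(40, "b")
        got = {r.id for r in consensus_intersect(a, b)}
        expected = {
            ra.id for ra in a if any(ra.region.overlaps(rb.region) for rb in b)
        }
        assert got == expected


class TestSummaryAndPipeline:
    def test_summary_arithmetic(self):
        rs = [
            CnvRegion("a", GenomicInterval("chr1", 0, 1000), {"S1": 1, "S2": 1}),
            CnvRegion("b", GenomicInterval("chr1", 5000, 8000),
                      {f"S{i}": 3 for i in range(4)}),
        ]
        df = region_summary(rs, n_samples=10)
        assert df.loc["mean_length_kb", "value"] == pytest.approx(2.0)
        assert df.loc["mean_cnv_per_cnvr", "value"] == pytest.approx(3.0)
        # mean CNVR per individual = total CNV / n_samples
        assert df.loc["mean_cnvr_per_individual", "value"] == pytest.approx(6 / 10)

    def test_caller_granularity_ordering(self, small_cohort):
        """Coarse caller: fewer regions, longer median length."""
        co = small_cohort
        a = merge_calls_to_cnvr(co.calls_a)
        b = merge_calls_to_cnvr(co.calls_b)
        med = lambda rs: np.median([r.region.length for r in rs])
        assert len(b) < len(a)
        assert med(b) > med(a)

    def test_noise_free_consensus_matches_truth(self, noisefree_cohort):
        """Without caller noise, consensus regions recover true CNVRs (Jaccard >= 0.95)."""
        co = noisefree_cohort
        regions, _, _ = run_consensus(co.calls_a, co.calls_b, len(co.samples))
        true_by_span = {(iv.start, iv.end): i for i, iv in enumerate(co.truth.cnvrs)}
        jaccards = []
        for r in regions:
            best = max(
                r.region.overlap_bp(iv)
                / (r.region.length + iv.length - r.region.overlap_bp(iv))
                for iv in co.truth.cnvrs
            )
            jaccards.append(best)
        assert np.mean(jaccards) >= 0.95
        # every multi-carrier true CNVR is recovered exactly
        recovered = {(r.region.start, r.region.end) for r in regions}
        for i, iv in enumerate(co.truth.cnvrs):
            if (co.truth.copies[i] != 2).sum() >= 2:
                assert (iv.start, iv.end) in recovered
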