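"""LD computation, haplotype assembly and copy-number regression."""

import numpy as np
import pytest

from afrocnv.core_io import GenomeLayout, GenomicInterval, SnpRecord, ValidationError
from afrocnv.taghap import (
    HaplotypeDef,
    build_haplotypes,
    candidate_window,
    copy_regression,
    informative_filter,
    ld_r2,
)

LAYOUT = GenomeLayout(("chr1",), (20_000,))


def snp(pos, chrom_alleles, missing=None):
    """SnpRecord from a flat list of per-chromosome alleles (len = 2n)."""
    alleles = np.asarray(chrom_alleles, dtype=np.int8)
    n = len(alleles) // 2
    if missing is None:
        missing = np.zeros(n, dtype=bool)
    return SnpRecord("chr1", pos, "A", "G", alleles.reshape(n, 2), np.asarray(missing))


class TestLdR2:
    def test_identical_vectors_give_one(self):
        a = snp(100, [0, 1] * 20)
        b = snp(200, [0, 1] * 20)
        assert ld_r2(a, b) == pytest.approx(1.0)

    def test_complement_gives_one(self):
        a = snp(100, [0, 1] * 20)
        b = snp(200, [1, 0] * 20)
        assert ld_r2(a, b) == pytest.approx(1.0)

    def test_textbook_d_squared_case(self):
        # 100 chromosomes: AB=40, Ab=10, aB=10, ab=40
        # D = 0.4 - 0.5*0.5 = 0.15; r2 = D^2/(pA qA pB qB) = 0.36
        hapA = [1] * 50 + [0] * 50
        hapB = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        assert ld_r2(snp(100, hapA), snp(200, hapB)) == pytest.approx(0.36)

    def test_monomorphic_flagged_nan(self):
        assert np.isnan(ld_r2(snp(100, [0] * 40), snp(200, [0, 1] * 20)))

    def test_missing_excluded_pairwise(self):
        # missing sample would otherwise break perfect LD
        a = snp(100, [0, 1] * 10, missing=[True] + [False] * 9)
        b = snp(200, [1, 1] + [0, 1] * 9, missing=[False] * 10)
        assert ld_r2(a, b) == pytest.approx(1.0)


class TestCandidateWindow:
    def test_left_clip(self):
        iv = GenomicInterval("chr1", 0, 10_000)
        assert candidate_window(iv, LAYOUT) == GenomicInterval("chr1", 0, 15_000)

    def test_both_flanks(self):
        iv = GenomicInterval("chr1", 6000, 8000)
        assert candidate_window(iv, LAYOUT) == GenomicInterval("chr1", 1000, 13_000)

    def test_zero_flank_identity(self):
        iv = GenomicInterval("chr1", 6000, 8000)
        assert candidate_window(iv, LAYOUT, flank=0) == iv


class TestBuildHaplotypes:
    def test_perfect_ld_pair_two_complementary_haplotypes(self):
        a = snp(100, [1, 1, 0, 0, 1, 0, 0, 0])
        b = snp(200, [1, 1, 0, 0, 1, 0, 0, 0])
        haps = build_haplotypes([a, b])
        assert len(haps) == 2
        by_label = {h.label: h for h in haps}
        assert set(by_label) == {"11", "00"}
        total = by_label["11"].dosage + by_label["00"].dosage
        assert (total == 2).all()

    def test_no_ld_no_haplotypes(self):
        a = snp(100, [1, 0, 1, 0, 1, 0, 0, 1])
        b = snp(200, [1, 1, 0, 0, 0, 1, 1, 0])
        assert ld_r2(a, b) < 0.8
        assert build_haplotypes([a, b]) == []

    def test_ld_window_limits_pairing(self):
        a = snp(100, [1, 1, 0, 0] * 3)
        b = snp(60_000, [1, 1, 0, 0] * 3)
        layout = GenomeLayout(("chr1",), (100_000,))
        assert build_haplotypes([a, b], ld_window=50_000) == []

    def test_clusters_match_brute_force_single_linkage(self):
        rng = np.random.default_rng(12)
        founders = rng.integers(0, 2, size=(3, 5))  # 3 founders x 5 SNPs
        choice = rng.integers(0, 3, size=80)  # 80 chromosomes
        mat = founders[choice]  # chromosomes x snps
        snps = [snp((i + 1) * 500, mat[:, i]) for i in range(5)]

        # oracle: brute-force single linkage over pairwise ld_r2 > 0.8
        n = len(snps)
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                r2 = ld_r2(snps[i], snps[j])
                if not np.isnan(r2) and r2 > 0.8:
                    adj[i].add(j)
                    adj[j].add(i)
        seen, clusters = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k])
            seen |= comp
            if len(comp) >= 2:
                clusters.append(frozenset(snps[k].pos for k in comp))

        haps = build_haplotypes(snps)
        got_clusters = {frozenset(h.positions) for h in haps}
        assert got_clusters == set(clusters)

        # dosage equals direct string counting
        for h in haps:
            idx = [k for k in range(n) if snps[k].pos in h.positions]
            sub = mat[:, idx]
            match = (sub == np.asarray(h.alleles)).all(axis=1)
            per_sample = match.reshape(-1, 2).sum(axis=1)
            assert (h.dosage == per_sample).all()
            assert h.chrom_count == int(match.sum())

    def test_rare_strings_dropped(self):
        # one chromosome carries a unique recombinant string
        a = snp(100, [1, 1, 1, 0, 0, 0])
        b = snp(200, [1, 1, 0, 0, 0, 0])
        # r2(a,b): 100 chroms would be needed for precision; here r2 ~ 0.5 so
        # force cluster with threshold 0.4 to exercise the noise floor
        haps = build_haplotypes([a, b], r2_threshold=0.4)
        labels = {h.label for h in haps}
        assert "10" not in labels  # single-chromosome string removed


class TestInformativeFilter:
    def hap(self, dosage):
        return HaplotypeDef((100,), (1,), np.asarray(dosage, dtype=float), 2)

    def test_identical_copy_carriers_dropped(self):
        h = self.hap([1, 1, 0, 0])
        assert informative_filter(h, [2, 2, 1, 3]) is False

    def test_varying_copy_carriers_kept(self):
        h = self.hap([1, 1, 0, 0])
        assert informative_filter(h, [1, 2, 2, 2]) is True

    def test_zero_carriers_is_an_error(self):
        h = self.hap([0, 0, 0])
        with pytest.raises(ValidationError):
            informative_filter(h, [2, 2, 2])


class TestCopyRegression:
    def test_perfect_fit(self):
        slope, r2, p = copy_regression([0, 1, 2, 0, 1, 2], [2, 3, 4, 2, 3, 4])
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-8

    def test_six_point_closed_form_oracle(self):
        # hand-solved normal equations for this fixture
        slope, r2, p = copy_regression([0, 1, 2, 0, 1, 2],
                                       [2.1, 2.9, 4.2, 1.9, 3.1, 3.8])
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(0.9708737864077669)
        assert p == pytest.approx(3.212663284598613e-4, rel=1e-9)

    def test_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, 30).astype(float)
        y = 2 + 0.5 * d + rng.normal(0, 0.2, 30)
        perm = rng.permutation(30)
        assert copy_regression(d, y) == pytest.approx(copy_regression(d[perm], y[perm]))

    def test_constant_dosage_refused(self):
        with pytest.raises(ValidationError):
            copy_regression([1, 1, 1, 1], [2, 3, 2, 3])

    def test_missing_dosage_excluded(self):
        d = [0, 1, 2, np.nan, 0, 1, 2]
        y = [2, 3, 4, 99, 2, 3, 4]
        slope, r2, _ = copy_regression(d, y)
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)


class TestTruthRecovery:
    def test_taggable_cnvrs_recovered_noise_free(self, noisefree_cohort):
        from afrocnv.consensus import merge_calls_to_cnvr, filter_singletons
        from afrocnv.taghap import tag_cnvrs

        co = noisefree_cohort
        regions = filter_singletons(merge_calls_to_cnvr(co.calls_a))
        assoc, tagged = tag_cnvrs(regions, co.snps, co.sample_ids, co.layout)
        span_to_region = {(r.region.start, r.region.end): r.id for r in regions}
        n_samples = len(co.samples)
        qualifying, hit = 0, 0
        for i, iv in enumerate(co.truth.cnvrs):
            carriers = (co.truth.copies[i] != 2).sum()
            if not co.truth.taggable[i] or carriers / n_samples <= 0.10:
                continue
            rid = span_to_region.get((iv.start, iv.end))
            if rid is None:
                continue
            qualifying += 1
            hit += bool(tagged[rid])
        assert qualifying >= 5
        assert hit / qualifying >= 0.9

    def test_true_copy_equals_two_plus_minus_tag_dosage(self, small_cohort):
        co = small_cohort
        for i, dosage in co.truth.tag_dosage.items():
            sign = -1 if co.truth.cnvr_type[i] == "del" else 1
            expected = np.clip(2 + sign * dosage, 0, None)
            assert (co.truth.copies[i] == expected).all()
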