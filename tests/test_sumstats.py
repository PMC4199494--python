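"""Statistic correctness against brute-force oracles and hand values."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_sample
from oracles import (ehh_bruteforce, fay_wu_h_bruteforce, ihh_bruteforce,
                     pi_bruteforce, reynolds_theta_bruteforce,
                     tajimas_d_bruteforce, watterson_bruteforce,
                     wc_theta_bruteforce)
from sweepabc.errors import UndefinedStatisticError
from sweepabc.haplotypes import WindowSpec
from sweepabc.io_formats import GeneticMap
from sweepabc import sumstats as ss

WHOLE = WindowSpec.whole_region()


# ---------------------------------------------------------------------------
# SFS statistics
# ---------------------------------------------------------------------------

class TestSFS:
    def test_pi_toy(self, toy_sample):
        # {00, 01, 11, 11}: 6 pairs with 7 differences in total
        assert ss.pairwise_diversity(toy_sample, WHOLE, "A") == pytest.approx(7 / 6)

    def test_pi_monomorphic(self):
        s = make_sample(np.zeros((4, 3)))
        assert ss.pairwise_diversity(s, WHOLE, "A") == 0.0

    def test_pi_duplication_changes_only_n_factor(self):
        rng = np.random.default_rng(0)
        m = (rng.random((5, 6)) < 0.5).astype(np.uint8)
        s1 = make_sample(m)
        s2 = make_sample(np.repeat(m, 2, axis=0))
        assert ss.pairwise_diversity(s1, WHOLE, "A") == pytest.approx(
            pi_bruteforce(m))
        assert ss.pairwise_diversity(s2, WHOLE, "A") == pytest.approx(
            pi_bruteforce(np.repeat(m, 2, axis=0)))

    def test_pi_needs_two_haplotypes(self):
        s = make_sample([[0, 1]])
        with pytest.raises(UndefinedStatisticError):
            ss.pairwise_diversity(s, WHOLE, "A")

    def test_watterson_hand_values(self):
        # S=7, n=4 -> 7 / (1 + 1/2 + 1/3)
        m = np.zeros((4, 7), np.uint8)
        m[0] = 1
        s = make_sample(m)
        assert ss.watterson_theta(s, WHOLE, "A") == pytest.approx(
            7 / (1 + 0.5 + 1 / 3))
        # S=0 -> 0; S=1, n=2 -> 1
        assert ss.watterson_theta(make_sample(np.zeros((4, 2))), WHOLE, "A") == 0
        assert ss.watterson_theta(make_sample([[0], [1]]), WHOLE, "A") == 1.0

    def test_tajimas_d_toy(self, toy_sample):
        d = ss.tajimas_d(toy_sample, WHOLE, "A")
        assert d == pytest.approx(tajimas_d_bruteforce(toy_sample.matrix))
        assert d == pytest.approx(0.59, abs=0.01)

    def test_tajimas_d_undefined_for_no_segregating_sites(self):
        with pytest.raises(UndefinedStatisticError):
            ss.tajimas_d(make_sample(np.zeros((4, 3))), WHOLE, "A")

    def test_fay_wu_hand_values(self):
        # single site, derived count 1 of 4: H = 0.5 - 1/6
        assert ss.fay_wu_h(make_sample([[1], [0], [0], [0]]), WHOLE, "A") == \
            pytest.approx(1 / 3)
        # derived count 3 of 4: H = 0.5 - 1.5
        assert ss.fay_wu_h(make_sample([[1], [1], [1], [0]]), WHOLE, "A") == \
            pytest.approx(-1.0)
        assert ss.fay_wu_h(make_sample(np.zeros((4, 2))), WHOLE, "A") == 0.0

    @given(st.integers(0, 2 ** 30))
    def test_sfs_statistics_match_bruteforce(self, seed):
        """Exhaustive-enumeration oracle equality on random small samples."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        s = int(rng.integers(1, 7))
        m = (rng.random((n, s)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        smp = make_sample(m)
        assert ss.pairwise_diversity(smp, WHOLE, "A") == pytest.approx(
            pi_bruteforce(m))
        assert ss.watterson_theta(smp, WHOLE, "A") == pytest.approx(
            watterson_bruteforce(m))
        assert ss.fay_wu_h(smp, WHOLE, "A") == pytest.approx(
            fay_wu_h_bruteforce(m))
        seg = any(0 < m[:, j].sum() < n for j in range(s))
        if seg and n >= 4:
            assert ss.tajimas_d(smp, WHOLE, "A") == pytest.approx(
                tajimas_d_bruteforce(m))

    def test_windows_clip_to_region(self):
        m = np.zeros((4, 5), np.uint8)
        m[0] = 1
        s = make_sample(m, positions=[0, 900, 1000, 1100, 4000],
                        focal=2, length=5000)
        w = WindowSpec("symmetric", 150, 150)
        # window [850, 1150] keeps the sites at 900, 1000, 1100
        assert ss.watterson_theta(s, w, "A") == pytest.approx(
            3 / (1 + 0.5 + 1 / 3))


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestFst:
    def test_fixed_difference_is_one(self):
        counts = [(10, 0, 0), (0, 0, 10)]
        _, theta = ss.wc_fst_site(counts)
        assert theta == pytest.approx(1.0)

    def test_equal_frequencies_nonpositive(self):
        counts = [(4, 8, 4), (4, 8, 4)]  # HWE p=0.5 both
        _, theta = ss.wc_fst_site(counts)
        assert theta <= 0

    def test_hwe_oracle_value(self):
        # p1=0.29, p2=0.97, 50 diploids each, HWE genotype counts
        def hwe(p, n):
            return ((1 - p) ** 2 * n, 2 * p * (1 - p) * n, p * p * n)
        counts = [hwe(0.29, 50), hwe(0.97, 50)]
        _, theta = ss.wc_fst_site(counts)
        assert theta == pytest.approx(wc_theta_bruteforce(counts))
        assert theta == pytest.approx(0.6596, abs=1e-3)

    def test_monomorphic_both_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ss.wc_fst_site([(5, 0, 0), (5, 0, 0)])

    @given(st.integers(0, 2 ** 30))
    def test_wc_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        counts = [tuple(rng.integers(0, 6, 3) + np.array([1, 0, 0])),
                  tuple(rng.integers(0, 6, 3) + np.array([0, 0, 1]))]
        comp = ss.wc_fst_components(counts)
        if comp.a + comp.b + comp.c != 0:
            assert comp.theta == pytest.approx(wc_theta_bruteforce(counts))

    def test_region_fst_single_site_reduces_to_site(self, two_pop_sample):
        s = two_pop_sample
        win = WindowSpec("symmetric", 40, 40)  # only the focal site
        gcounts = ss.genotype_counts_at(s, s.focal_index)
        _, site_theta = ss.wc_fst_site(gcounts)
        assert ss.region_fst(s, win) == pytest.approx(site_theta)

    def test_region_fst_is_ratio_of_sums(self, two_pop_sample):
        s = two_pop_sample
        num = den = 0.0
        for j in range(s.n_sites):
            comp = ss.wc_fst_components(ss.genotype_counts_at(s, j))
            tot = comp.a + comp.b + comp.c
            if tot != 0:
                num += comp.a
                den += tot
        assert ss.region_fst(s, WHOLE) == pytest.approx(num / den)

    def test_region_fst_all_monomorphic_undefined(self):
        m = np.zeros((8, 3), np.uint8)
        s = make_sample(m, pops=["A"] * 4 + ["B"] * 4)
        with pytest.raises(UndefinedStatisticError):
            ss.region_fst(s, WHOLE)

    def test_reynolds_examples(self):
        assert ss.reynolds_fst_site([(20, 20), (20, 0)]) == pytest.approx(1.0)
        assert ss.reynolds_fst_site([(20, 10), (20, 10)]) <= 0
        assert ss.reynolds_fst_site([(20, 4), (20, 16)]) == pytest.approx(
            reynolds_theta_bruteforce(20, 4, 20, 16))


# ---------------------------------------------------------------------------
# EHH family
# ---------------------------------------------------------------------------

def _map_const(rate=1.0, L=1000.0):
    return GeneticMap.constant(rate, L)


class TestEHH:
    def test_target_equals_core_is_one(self, two_pop_sample):
        s = two_pop_sample
        assert ss.ehh(s, "B", s.focal_index, 1, s.focal_index) == 1.0

    def test_identical_carriers_one(self):
        m = np.tile([1, 0, 1, 1], (4, 1)).astype(np.uint8)
        s = make_sample(m)
        assert ss.ehh(s, "A", 0, 1, 3) == 1.0

    def test_four_carriers_pattern(self):
        # carrier interval patterns {00, 00, 01, 11}: one identical pair of 6
        m = np.array([[1, 0, 0], [1, 0, 0], [1, 0, 1], [1, 1, 1]], np.uint8)
        s = make_sample(m)
        assert ss.ehh(s, "A", 0, 1, 2) == pytest.approx(1 / 6)

    def test_fewer_than_two_carriers_undefined(self):
        s = make_sample([[1, 0], [0, 1], [0, 0]])
        with pytest.raises(UndefinedStatisticError):
            ss.ehh(s, "A", 0, 1, 1)

    @given(st.integers(0, 2 ** 30))
    def test_ehh_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        s_ = int(rng.integers(2, 7))
        m = (rng.random((n, s_)) < 0.5).astype(np.uint8)
        core = int(rng.integers(0, s_))
        allele = int(m[:, core].max())
        target = int(rng.integers(0, s_))
        car = m[m[:, core] == allele]
        if car.shape[0] < 2:
            return
        smp = make_sample(m)
        cols = list(range(min(core, target), max(core, target) + 1))
        assert ss.ehh(smp, "A", core, allele, target) == pytest.approx(
            ehh_bruteforce(car, cols))

    def test_ihh_identical_carriers_equals_genetic_length(self):
        m = np.tile([0, 1, 0, 0], (4, 1)).astype(np.uint8)
        s = make_sample(m, positions=[100, 200, 300, 400], length=1000)
        res = ss.ihh(s, "A", 1, 1, _map_const(2.0, 1000.0))
        assert res.edge_truncated
        assert res.value == pytest.approx(2.0 * 1000.0 / 1e6)

    def test_ihh_drops_to_zero_adjacent(self):
        # EHH hits 0 at the first site on both sides: two closing trapezoids
        m = np.array([[1, 1, 0], [0, 1, 1], [1, 1, 0], [0, 1, 1]], np.uint8)
        m[0, 0], m[2, 0] = 1, 0  # carriers split on both flanks
        m = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 1], [1, 1, 0]], np.uint8)
        s = make_sample(m, positions=[0, 500, 1000], length=1000)
        gmap = _map_const(1.0, 1000.0)
        res = ss.ihh(s, "A", 1, 1, gmap)
        g = gmap.genetic_position(np.array([0.0, 500.0, 1000.0]))
        e_left = ehh_bruteforce(m, [0, 1])
        e_right = ehh_bruteforce(m, [1, 2])
        expected = 0.5 * (1 + e_left) * (g[1] - g[0]) + \
            0.5 * (1 + e_right) * (g[2] - g[1])
        assert res.value == pytest.approx(
            ihh_bruteforce(s, "A", 1, 1, gmap))
        if e_left < 0.05 and e_right < 0.05:
            assert res.value == pytest.approx(expected)

    def test_ihh_linear_in_map_rate(self, two_pop_sample):
        s = two_pop_sample
        L = s.region_length
        v1 = ss.ihh(s, "B", s.focal_index, 1, _map_const(1.0, L)).value
        v2 = ss.ihh(s, "B", s.focal_index, 1, _map_const(2.0, L)).value
        assert v2 == pytest.approx(2 * v1)

    @given(st.integers(0, 2 ** 30))
    def test_ihh_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        s_ = int(rng.integers(2, 7))
        m = (rng.random((n, s_)) < 0.5).astype(np.uint8)
        core = int(rng.integers(0, s_))
        allele = int(m[:, core].max())
        if (m[:, core] == allele).sum() < 2:
            return
        smp = make_sample(m, length=s_ * 100.0)
        gmap = _map_const(1.5, s_ * 100.0)
        assert ss.ihh(smp, "A", core, allele, gmap).value == pytest.approx(
            ihh_bruteforce(smp, "A", core, allele, gmap))

    def test_ihs_symmetric_structure_is_zero(self):
        # ancestral and derived carriers have mirror-identical haplotypes
        m = np.array([
            [1, 1, 0, 1, 1], [1, 1, 0, 1, 0], [0, 1, 0, 0, 1],
            [1, 0, 1, 1, 1], [1, 0, 1, 1, 0], [0, 0, 1, 0, 1]], np.uint8)
        s = make_sample(m, length=500.0)
        assert ss.ihs(s, "A", 2, _map_const(1.0, 500.0), min_maf=0.0) == \
            pytest.approx(0.0)

    def test_ihs_maf_filter(self, two_pop_sample):
        s = two_pop_sample
        m = s.matrix.copy()
        m[:, 3] = 0
        m[0, 3] = 1
        s2 = make_sample(m, positions=s.positions, pops=list(s.pop_labels),
                         focal=s.focal_index, length=s.region_length)
        with pytest.raises(UndefinedStatisticError):
            ss.ihs(s2, "A", 3, _map_const(1.0, s.region_length))

    def test_ihs_toy_equals_oracle_composition(self):
        rng = np.random.default_rng(3)
        m = (rng.random((6, 5)) < 0.5).astype(np.uint8)
        m[:3, 2] = 1
        m[3:, 2] = 0
        s = make_sample(m, length=500.0)
        gmap = _map_const(1.0, 500.0)
        expected = np.log(ihh_bruteforce(s, "A", 2, 0, gmap)
                          / ihh_bruteforce(s, "A", 2, 1, gmap))
        assert ss.ihs(s, "A", 2, gmap, min_maf=0.0) == pytest.approx(expected)

    def test_xpehh_identical_populations_zero(self, two_pop_sample):
        s = two_pop_sample
        a = ss.single_pop_view(s, "A")
        gmap = _map_const(1.0, s.region_length)
        assert ss.xpehh(a, a, s.focal_index, gmap) == pytest.approx(0.0)

    def test_xpehh_antisymmetric(self, two_pop_sample):
        s = two_pop_sample
        a = ss.single_pop_view(s, "A")
        b = ss.single_pop_view(s, "B")
        gmap = _map_const(1.0, s.region_length)
        assert ss.xpehh(a, b, s.focal_index, gmap) == pytest.approx(
            -ss.xpehh(b, a, s.focal_index, gmap))

    def test_xpehh_monomorphic_block_positive(self):
        rng = np.random.default_rng(5)
        mono = np.tile([1, 1, 0, 1, 1], (6, 1)).astype(np.uint8)
        div = (rng.random((6, 5)) < 0.5).astype(np.uint8)
        div[:, 2] = rng.permutation([1, 1, 1, 0, 0, 0])
        sa = make_sample(mono, length=500.0)
        sb = make_sample(div, pops=["B"] * 6, length=500.0)
        gmap = _map_const(1.0, 500.0)
        v = ss.xpehh(sa, sb, 2, gmap)
        expected = np.log(ihh_bruteforce(sa, "A", 2, None, gmap)
                          / ihh_bruteforce(sb, "B", 2, None, gmap))
        assert v > 0
        assert v == pytest.approx(expected)


# ---------------------------------------------------------------------------
# standardisation / p-values
# ---------------------------------------------------------------------------

class TestStandardise:
    def test_bin_moments(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20_000)
        freqs = rng.uniform(0.0, 1.0, size=20_000)
        out, merged = ss.standardize_binned(scores, freqs)
        assert merged == []  # every 1% bin is well populated at this size
        idx = np.minimum((freqs / 0.01).astype(int), 99)
        for b in np.unique(idx):
            sel = idx == b
            assert abs(out[sel].mean()) < 1e-9
            assert abs(out[sel].std() - 1) < 1e-9

    def test_small_bins_merged_and_flagged(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        freqs = np.array([0.101, 0.102, 0.103, 0.108, 0.55])
        out, merged = ss.standardize_binned(scores, freqs)
        assert merged  # the lone 0.55 entry joined the populated bin
        assert np.isfinite(out).all()

    def test_empirical_pvalue_floor(self):
        dist = ss.ScoreDistribution(np.arange(999, dtype=float))
        p = ss.empirical_pvalue(2000.0, dist)
        assert p.is_floor and p.p == pytest.approx(1 / 999)

    def test_empirical_pvalue_median(self):
        dist = ss.ScoreDistribution(np.arange(1000, dtype=float))
        p = ss.empirical_pvalue(500.0, dist)
        assert p.p == pytest.approx(0.5)
        assert not p.is_floor

    def test_empirical_pvalue_ties(self):
        vals = np.array([1.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        p = ss.empirical_pvalue(3.0, ss.ScoreDistribution(vals))
        assert p.p == pytest.approx(4 / 6)  # 3 ties + one larger
        pl = ss.empirical_pvalue(3.0, ss.ScoreDistribution(vals, tail="lower"))
        assert pl.p == pytest.approx(5 / 6)


# ---------------------------------------------------------------------------
# summary vectors
# ---------------------------------------------------------------------------

class TestSummaryVector:
    def test_registry_completeness_and_consistency(self, two_pop_sample):
        s = two_pop_sample
        gmap = _map_const(1.0, s.region_length)
        sv = ss.compute_summary_vector(s, gmap)
        reg = ss.default_registry()
        assert list(sv.values) == reg
        assert len(reg) == 22
        # entries equal the standalone operations
        assert sv.values["pi_w4kb_p1"] == pytest.approx(
            ss.pairwise_diversity(s, WindowSpec.symmetric_4kb(), "A"))
        assert sv.values["fwH_w8kb_p2"] == pytest.approx(
            ss.fay_wu_h(s, WindowSpec.asymmetric_8kb(), "B"))
        assert sv.values["fst_region"] == pytest.approx(
            ss.region_fst(s, WHOLE))
        hapA = s.haplotypes_of("A")[:, s.focal_index]
        hapB = s.haplotypes_of("B")[:, s.focal_index]
        assert sv.values["fst_site"] == pytest.approx(
            reynolds_theta_bruteforce(
                hapA.size, hapA.sum(), hapB.size, hapB.sum()))
        a = ss.single_pop_view(s, "A")
        b = ss.single_pop_view(s, "B")
        assert sv.values["xpehh_site"] == pytest.approx(
            ss.xpehh(b, a, s.focal_index, gmap))

    def test_focal_frequencies(self):
        rng = np.random.default_rng(2)
        m = (rng.random((200, 9)) < 0.4).astype(np.uint8)
        col = np.zeros(200, np.uint8)
        col[:29] = 1          # 29/100 derived in population 1
        col[100:197] = 1      # 97/100 derived in population 2
        m[:, 4] = col
        s = make_sample(m, pops=["A"] * 100 + ["B"] * 100, focal=4,
                        length=900.0)
        sv = ss.compute_summary_vector(s, _map_const(1.0, 900.0))
        assert sv.values["daf_p1"] == pytest.approx(0.29)
        assert sv.values["daf_p2"] == pytest.approx(0.97)

    def test_undefined_entries_flagged_not_zero(self):
        # monomorphic population 2 in the 4 kb window -> Tajima's D undefined
        m = np.zeros((8, 3), np.uint8)
        m[0:2, 1] = 1
        m[4:, 1] = 1
        m[0, 0] = 1
        s = make_sample(m, positions=[10.0, 50.0, 90.0],
                        pops=["A"] * 4 + ["B"] * 4, focal=1, length=100.0)
        sv = ss.compute_summary_vector(s, _map_const(1.0, 100.0))
        assert "tajD_w4kb_p2" in sv.flags
        assert np.isnan(sv.values["tajD_w4kb_p2"])
        assert not sv.is_complete
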