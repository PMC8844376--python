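"""Adjacency distances, the mean-difference statistic, clustering, and
haplotype-derived multi-InDel spectra."""

import numpy as np
import pytest

from mmindel.mai_filter import FilterParams
from mmindel.multi_indel import (
    DistanceHistogram, adjacent_distance_histogram, cluster_indels,
    filter_multi_indels, haplotype_spectrum, mean_difference_series,
    pair_distance, suggest_gap_threshold,
)
from conftest import make_site
from helpers_oracles import best_span_clustering, mdv_direct


def sites_at(positions, ref_lens=None, chrom="chr1"):
    ref_lens = ref_lens or [1] * len(positions)
    return [make_site(chrom, p, "A" * rl, ("A" * rl + "T",))
            for p, rl in zip(positions, ref_lens)]


class TestDistances:
    def test_pair_distance_counts_intervening_bases(self):
        up, down = sites_at([100, 105])
        assert pair_distance(up, down) == 4

    def test_deletion_span_shortens_distance(self):
        up, down = sites_at([100, 105], ref_lens=[3, 1])
        assert pair_distance(up, down) == 2

    def test_single_site_contributes_nothing(self):
        hist = adjacent_distance_histogram(sites_at([100]))
        assert hist.counts == {}

    def test_planted_gaps_recovered(self):
        # consecutive anchors with ref len 1: distance = delta - 2... build
        # explicitly: gaps {3, 3, 50}
        pos = [100]
        for gap in (3, 3, 50):
            pos.append(pos[-1] + 1 + gap)  # ref_end = pos, next = end+gap+1
        hist = adjacent_distance_histogram(sites_at(pos))
        assert hist.counts == {3: 2, 50: 1}

    def test_chromosomes_do_not_chain(self):
        s = sites_at([100, 105]) + sites_at([200, 204], chrom="chr2")
        hist = adjacent_distance_histogram(s)
        assert hist.counts == {4: 1, 3: 1}


class TestMeanDifference:
    def test_printed_formula_example(self):
        h = DistanceHistogram({8: 100, 9: 80, 11: 40, 12: 20})
        mdv = mean_difference_series(h, s_max=12)
        assert mdv[10] == 60.0  # (100+80)/2 - (40+20)/2

    def test_flat_histogram_is_zero(self):
        h = DistanceHistogram({s: 7 for s in range(3, 50)})
        mdv = mean_difference_series(h, s_max=45)
        assert all(mdv[s] == 0.0 for s in range(5, 44))

    def test_matches_direct_arithmetic_on_random_histograms(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            counts = {int(s): int(rng.integers(0, 500))
                      for s in rng.integers(1, 100, size=40)}
            h = DistanceHistogram(counts)
            mdv = mean_difference_series(h, s_max=105)
            for s in range(1, 106):
                assert mdv[s] == mdv_direct(counts, s)


class TestGapThreshold:
    def test_rule_application(self):
        mdv = {1: 60, 2: 40, 3: 30, 4: 26, 5: 10, 6: 0}
        assert suggest_gap_threshold(mdv, cutoff=25) == 4

    def test_no_distance_qualifies(self):
        assert suggest_gap_threshold({1: 10, 2: 5, 3: 2}, cutoff=25) == 0

    def test_constructed_decay_histogram_yields_twenty(self):
        # N_s = round(505 * 0.93^s) + 50: the MDV of the geometric part is
        # 505 * 0.2183 * 0.93^s, which crosses 25 between s = 20 and 21
        h = DistanceHistogram({s: round(505 * 0.93 ** s) + 50
                               for s in range(1, 101)})
        mdv = mean_difference_series(h, s_max=100)
        assert suggest_gap_threshold(mdv, cutoff=25.0) == 20


class TestClustering:
    def test_chaining_with_consecutive_gaps(self):
        pos = [100]
        for gap in (5, 18, 30):
            pos.append(pos[-1] + 1 + gap)
        clusters = cluster_indels(sites_at(pos), max_gap=20)
        assert [len(c) for c in clusters] == [3]
        assert [s.pos for s in clusters[0]] == pos[:3]

    def test_empty_input(self):
        assert cluster_indels([], max_gap=20) == []

    def test_span_mode_rejects_wide_triple(self):
        pos = [100]
        for gap in (15, 15):
            pos.append(pos[-1] + 1 + gap)
        span = cluster_indels(sites_at(pos), max_gap=20, mode="span")
        chain = cluster_indels(sites_at(pos), max_gap=20)
        assert [len(c) for c in chain] == [3]
        assert [len(c) for c in span] == [2]  # greedy keeps the left pair
        assert [s.pos for s in span[0]] == pos[:2]

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pos = np.cumsum(rng.integers(2, 40, size=12)) + 100
            for mode in ("consecutive_gap", "span"):
                clusters = cluster_indels(sites_at(list(pos)), max_gap=20,
                                          mode=mode)
                seen = [s.pos for c in clusters for s in c]
                assert len(seen) == len(set(seen))  # no site reused

    def test_translation_invariance(self):
        rng = np.random.default_rng(21)
        pos = list(np.cumsum(rng.integers(2, 30, size=10)) + 100)
        a = cluster_indels(sites_at(pos), max_gap=20)
        b = cluster_indels(sites_at([p + 10_000 for p in pos]), max_gap=20)
        assert [[s.pos for s in c] for c in b] == \
            [[s.pos + 10_000 for s in c] for c in a]

    def test_span_mode_matches_exhaustive_oracle(self):
        """Greedy span clustering equals the exhaustively-determined
        left-to-right maximal contiguous partition on <= 6 sites."""
        rng = np.random.default_rng(33)
        for _ in range(300):
            n = int(rng.integers(2, 7))
            pos = list(np.cumsum(rng.integers(2, 30, size=n)) + 100)
            sites = sites_at(pos)
            got = [[s.pos for s in c]
                   for c in cluster_indels(sites, max_gap=20, mode="span")]
            pe = [(s.pos, s.ref_end) for s in sites]
            want = [[pos[i] for i in grp]
                    for grp in best_span_clustering(pe, max_gap=20)]
            assert got == want


class TestHaplotypeSpectrum:
    def _pair(self, combos, n=10):
        """Two bi-allelic sites whose 2n haplotypes follow ``combos``
        (list of (a, b) codes, one per haplotype, cycled)."""
        haps = [combos[i % len(combos)] for i in range(2 * n)]
        gt_a = [h[0] for h in haps]
        gt_b = [h[1] for h in haps]
        return [make_site("chr1", 100, "A", ("AT",), gt_a, n_samples=n),
                make_site("chr1", 110, "A", ("AG",), gt_b, n_samples=n)]

    def test_three_of_four_combinations(self, five_pop_panel):
        cluster = self._pair([(0, 0), (1, 0), (0, 1)],
                             n=len(five_pop_panel))
        spec = haplotype_spectrum(cluster, five_pop_panel)
        assert spec.alleles == ["0-0", "0-1", "1-0"]
        assert spec.global_freq.sum() == pytest.approx(1.0)

    def test_fully_linked_pair_has_two_alleles(self, five_pop_panel):
        cluster = self._pair([(0, 0), (1, 1)], n=len(five_pop_panel))
        spec = haplotype_spectrum(cluster, five_pop_panel)
        assert spec.alleles == ["0-0", "1-1"]
        markers = filter_multi_indels([cluster], five_pop_panel)
        assert markers == []

    def test_missing_haplotype_dropped(self, five_pop_panel):
        n = len(five_pop_panel)
        cluster = self._pair([(0, 0), (1, 0), (0, 1)], n=n)
        cluster[0].genotypes[0, 0] = -1
        spec = haplotype_spectrum(cluster, five_pop_panel)
        assert spec.global_freq.sum() == pytest.approx(1.0)
        # denominator shrank by one haplotype
        counts = spec.global_freq * (2 * n - 1)
        assert np.allclose(counts, np.round(counts))

    def test_filter_keeps_three_valid_alleles(self, five_pop_panel):
        cluster = self._pair([(0, 0)] * 6 + [(1, 0)] * 3 + [(0, 1)],
                             n=len(five_pop_panel))
        (m,) = filter_multi_indels([cluster], five_pop_panel,
                                   FilterParams())
        assert m.n_valid_alleles == 3
        assert m.gaps == [9]

    def test_near_monomorphic_cluster_rejected(self, five_pop_panel):
        cluster = self._pair([(0, 0)] * 39 + [(1, 0)],
                             n=len(five_pop_panel))  # 1/40 = 0.025 -> 2 valid
        assert filter_multi_indels([cluster], five_pop_panel) == []

    def test_two_biallelic_members_bound_to_four_alleles(self, desk_result):
        res, _ = desk_result
        for m in res.mi_markers:
            if len(m.member_sites) == 2 and all(
                    len(s.alts) == 1 for s in m.member_sites):
                assert 1 <= len(m.spectrum.alleles) <= 4
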