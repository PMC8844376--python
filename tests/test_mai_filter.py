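"""Allele spectra, nomination, and the multi-allelic marker criteria."""

import numpy as np
import pytest

from mmindel.mai_filter import (
    AlleleSpectrum, FilterParams, allele_count_histogram,
    allele_frequencies, allele_rank_summaries, filter_multi_allelic,
)
from conftest import make_site


def _random_context_reference(length=2000, seed=2):
    """A reference that classifies as random context nearly everywhere."""
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=length))}


class TestAlleleFrequencies:
    def test_haplotype_counting(self, four_sample_panel):
        s = make_site(pos=100, ref="AT", alts=("A", "ATT"),
                      gt=[0, 0, 1, 2, 0, 0, 0, 0])
        spec = allele_frequencies(s, four_sample_panel)
        assert spec.global_freq.tolist() == [0.75, 0.125, 0.125]

    def test_four_haplotypes_example(self, four_sample_panel):
        s = make_site(pos=100, ref="AT", alts=("A", "ATT"),
                      gt=[0, 0, 1, 2, -1, -1, -1, -1])
        spec = allele_frequencies(s, four_sample_panel)
        # only 4 usable haplotypes: (0,0,1,2)
        assert spec.global_freq.tolist() == [0.5, 0.25, 0.25]

    def test_all_reference_degenerate(self, four_sample_panel):
        s = make_site(alts=("AT",), gt=[0] * 8)
        spec = allele_frequencies(s, four_sample_panel)
        assert spec.global_freq.tolist() == [1.0, 0.0]

    def test_denominator_is_twice_sample_count(self, five_pop_panel):
        n = len(five_pop_panel)
        gt = [0] * (2 * n)
        gt[0] = 1
        s = make_site(alts=("AT",), gt=gt, n_samples=n)
        spec = allele_frequencies(s, five_pop_panel)
        assert spec.global_freq[1] == pytest.approx(1 / (2 * n))

    def test_missing_dropped_from_pop_denominator(self, four_sample_panel):
        s = make_site(alts=("AT",), gt=[1, -1, 0, 0, 0, 0, 0, 0])
        spec = allele_frequencies(s, four_sample_panel)
        assert spec.pop_freq["AFR"].tolist() == [0.0, 1.0]

    def test_no_usable_haplotypes_is_error(self, four_sample_panel):
        s = make_site(alts=("AT",), gt=[-1] * 8)
        with pytest.raises(ValueError, match="no usable haplotypes"):
            allele_frequencies(s, four_sample_panel)

    def test_spectrum_requires_unit_sum(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AlleleSpectrum("m", ["A", "B"], [0.5, 0.4], {})


class TestNomination:
    def _spec(self, freqs, keys=None):
        keys = keys or [f"K{i}" for i in range(len(freqs))]
        return AlleleSpectrum("m", keys, np.array(freqs),
                              {}).nominate()

    def test_descending_frequency(self):
        spec = self._spec([0.2, 0.7, 0.1], ["B", "A", "C"])
        assert spec.by_rank() == [(1, "A", 0.7), (2, "B", 0.2), (3, "C", 0.1)]

    def test_tie_breaks_lexicographically(self):
        spec = self._spec([0.5, 0.5], ["B", "A"])
        assert [a for _, a, _ in spec.by_rank()] == ["A", "B"]

    def test_ranks_beyond_six_pooled_in_summaries(self):
        class M:
            n_valid_alleles = 8
            spectrum = self._spec([0.3, 0.2, 0.15, 0.1, 0.1, 0.05, 0.05,
                                   0.05])
        summ = allele_rank_summaries([M()], max_rank=6)
        assert set(summ) == {1, 2, 3, 4, 5, 6, 0}  # 0 = "others" bucket
        assert summ[0]["n"] == 2


class TestFilterMultiAllelic:
    def _run(self, sites, ref, panel, **kw):
        funnel = {}
        markers = filter_multi_allelic(sites, ref, panel,
                                       FilterParams(**kw), funnel=funnel)
        return markers, funnel

    def _qualifying_site(self, reference, panel, freqs=(0.5, 0.3, 0.2)):
        """ref + deletion + insertion at pos 1000 with given frequencies.

        The insertion sequence is searched so the whole site genuinely
        classifies as random context.
        """
        from itertools import product
        from mmindel.seq_class import site_is_random_context

        seq = reference["chr1"]
        pos = 1000
        a = seq[pos - 1]
        d = seq[pos: pos + 4]
        n = len(panel)
        counts = [round(f * 2 * n) for f in freqs]
        counts[0] = 2 * n - sum(counts[1:])
        gt = sum(([i] * c for i, c in enumerate(counts)), [])
        for ins in ("".join(t) for t in product("ACGT", repeat=3)):
            site = make_site("chr1", pos, a + d, (a, a + ins + d), gt,
                             n_samples=n)
            if site_is_random_context(site, reference):
                return site
        raise AssertionError("no random insertion found at fixture locus")

    def test_qualifying_site_kept(self, five_pop_panel):
        ref = _random_context_reference()
        s = self._qualifying_site(ref, five_pop_panel)
        markers, funnel = self._run([s], ref, five_pop_panel)
        assert len(markers) == 1
        assert markers[0].n_valid_alleles == 3
        assert funnel["kept"] == 1

    def test_low_frequency_allele_not_valid(self, five_pop_panel):
        ref = _random_context_reference()
        # third allele at 1/40 of haplotypes would pass; at 0 of 40 fails
        s = self._qualifying_site(ref, five_pop_panel, (0.75, 0.25, 0.0))
        markers, funnel = self._run([s], ref, five_pop_panel)
        assert markers == []
        assert funnel["lt_min_valid_alleles"] == 1

    def test_expansion_allele_rejected(self, five_pop_panel):
        ref = _random_context_reference()
        s = self._qualifying_site(ref, five_pop_panel)
        s.alts[1] = s.alts[0][:1] + "ATATAT" + s.ref[1:]  # tandem array alt
        s.kinds = []
        s.__post_init__()
        markers, funnel = self._run([s], ref, five_pop_panel)
        assert markers == []
        assert funnel["not_random"] == 1

    def test_single_indel_alt_rejected(self, five_pop_panel):
        ref = _random_context_reference()
        n = len(five_pop_panel)
        pos = 1000
        a = ref["chr1"][pos - 1]
        s = make_site("chr1", pos, a, (a + "TCG",), [0, 1] * n, n_samples=n)
        _, funnel = self._run([s], ref, five_pop_panel)
        assert funnel["lt2_indel_alts"] == 1

    def test_non_autosome_rejected(self, five_pop_panel):
        ref = {"chrX": _random_context_reference()["chr1"]}
        s = self._qualifying_site({"chr1": ref["chrX"]}, five_pop_panel)
        s.chrom = "chrX"
        _, funnel = self._run([s], ref, five_pop_panel)
        assert funnel["not_autosome"] == 1

    def test_monotone_in_af_min(self, five_pop_panel):
        """Raising the frequency threshold never adds markers."""
        ref = _random_context_reference()
        rng = np.random.default_rng(31)
        sites = []
        for f3 in rng.uniform(0.0, 0.2, size=12):
            f2 = rng.uniform(0.1, 0.3)
            sites.append(self._qualifying_site(
                ref, five_pop_panel, (1 - f2 - f3, f2, f3)))
        prev = None
        for af_min in (0.005, 0.01, 0.05, 0.1, 0.2):
            got = {id(m.site) for m in self._run(
                sites, ref, five_pop_panel, af_min=af_min)[0]}
            if prev is not None:
                assert got <= prev
            prev = got

    def test_histogram_sums_to_marker_count(self):
        class M:
            def __init__(self, n):
                self.n_valid_alleles = n
        hist = allele_count_histogram([M(3), M(3), M(4)])
        assert hist == {3: 2, 4: 1}
        assert sum(hist.values()) == 3

    def test_rank_frequencies_non_increasing(self, desk_result):
        res, _ = desk_result
        for m in res.ma_markers:
            freqs = [f for _, _, f in m.spectrum.by_rank()]
            assert all(a >= b for a, b in zip(freqs, freqs[1:]))
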