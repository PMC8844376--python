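"""Allele spectra and the multi-allelic InDel marker filter.

A site qualifies as a multi-allelic InDel marker when it is autosomal, at
least two of its alternate alleles are insertions/deletions, every indel
allele (and its 12-bp flanks) is a random sequence, and at least three of
its alleles (reference included; SNP alts excluded from the allele set but
kept in frequency denominators) have global frequency above ``af_min``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import IndelSite, Panel, VariantKind, POPULATIONS, is_autosome
from .seq_class import ClassParams, DEFAULT_PARAMS, site_is_random_context


@dataclass
class AlleleSpectrum:
    """Allele keys with global and per-population frequencies and ranks.

    ``global_freq`` sums to 1 over *all* alleles of the marker (valid or
    not).  ``rank`` is the 1-based nomination order: descending global
    frequency, ties broken lexicographically by allele key.
    """

    marker_id: str
    alleles: list[str]
    global_freq: np.ndarray
    pop_freq: dict[str, np.ndarray]
    rank: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.global_freq = np.asarray(self.global_freq, dtype=float)
        if abs(self.global_freq.sum() - 1.0) > 1e-9:
            raise ValueError("global allele frequencies must sum to 1")

    def nominate(self) -> "AlleleSpectrum":
        order = sorted(range(len(self.alleles)),
                       key=lambda i: (-self.global_freq[i], self.alleles[i]))
        rank = np.empty(len(order), dtype=int)
        for r, i in enumerate(order, start=1):
            rank[i] = r
        self.rank = rank
        return self

    def by_rank(self) -> list[tuple[int, str, float]]:
        """(rank, allele, global frequency) sorted by rank."""
        if self.rank is None:
            self.nominate()
        return sorted(
            ((int(r), a, float(f)) for r, a, f in
             zip(self.rank, self.alleles, self.global_freq)),
            key=lambda t: t[0])


def allele_frequencies(site: IndelSite, panel: Panel,
                       marker_id: str | None = None) -> AlleleSpectrum:
    """Haplotype-count frequencies of every allele, global and per population.

    Missing haplotypes are dropped from the denominators (never imputed).
    """
    gt = site.genotypes
    n_alleles = len(site.alleles)
    valid = gt >= 0
    total = int(valid.sum())
    if total == 0:
        raise ValueError(f"no usable haplotypes at {site.chrom}:{site.pos}")
    counts = np.bincount(gt[valid].ravel(), minlength=n_alleles)
    pop_freq: dict[str, np.ndarray] = {}
    for pop in POPULATIONS:
        m = panel.pop_mask(pop)
        sub = gt[m]
        subvalid = sub >= 0
        denom = int(subvalid.sum())
        if denom == 0:
            pop_freq[pop] = np.full(n_alleles, np.nan)
        else:
            pop_freq[pop] = (np.bincount(sub[subvalid].ravel(),
                                         minlength=n_alleles) / denom)
    mid = marker_id or f"{site.chrom}:{site.pos}"
    return AlleleSpectrum(mid, list(site.alleles), counts / total,
                          pop_freq).nominate()


def nominate_alleles(spectrum: AlleleSpectrum) -> AlleleSpectrum:
    """Assign nomination ranks 1..k by descending global frequency."""
    return spectrum.nominate()


@dataclass
class FilterParams:
    af_min: float = 0.01
    min_valid_alleles: int = 3
    strict_greater: bool = True  # frequency comparison: > af_min (vs >=)

    def is_valid(self, freq: float) -> bool:
        return freq > self.af_min if self.strict_greater else freq >= self.af_min


@dataclass
class MultiAllelicMarker:
    site: IndelSite
    spectrum: AlleleSpectrum
    n_valid_alleles: int
    max_allele_len: int

    @property
    def marker_id(self) -> str:
        return self.spectrum.marker_id

    def valid_allele_keys(self, params: FilterParams) -> list[str]:
        keys = []
        for i in self._allele_set_indices():
            if params.is_valid(self.spectrum.global_freq[i]):
                keys.append(self.spectrum.alleles[i])
        return keys

    def _allele_set_indices(self) -> list[int]:
        # reference plus indel alts; SNP/OTHER alts are not marker alleles
        return [0] + self.site.indel_alt_indices()


def _site_valid_count(site: IndelSite, spectrum: AlleleSpectrum,
                      params: FilterParams) -> int:
    idx = [0] + site.indel_alt_indices()
    return int(sum(bool(params.is_valid(spectrum.global_freq[i]))
                   for i in idx))


def filter_multi_allelic(
    sites: Iterable[IndelSite],
    reference: Mapping[str, str],
    panel: Panel,
    params: FilterParams | None = None,
    class_params: ClassParams = DEFAULT_PARAMS,
    funnel: dict | None = None,
) -> list[MultiAllelicMarker]:
    """Apply the multi-allelic InDel criteria to a normalized site stream.

    ``funnel``, if given, accumulates per-criterion rejection counts so the
    filter cascade is auditable.
    """
    params = params or FilterParams()
    out: list[MultiAllelicMarker] = []
    counts = funnel if funnel is not None else {}
    for key in ("input", "not_autosome", "lt2_indel_alts", "not_random",
                "lt_min_valid_alleles", "kept"):
        counts.setdefault(key, 0)
    for site in sites:
        counts["input"] += 1
        if not is_autosome(site.chrom):
            counts["not_autosome"] += 1
            continue
        if site.n_indel_alts < 2:
            counts["lt2_indel_alts"] += 1
            continue
        if not site_is_random_context(site, reference, class_params):
            counts["not_random"] += 1
            continue
        spectrum = allele_frequencies(site, panel)
        n_valid = _site_valid_count(site, spectrum, params)
        if n_valid < params.min_valid_alleles:
            counts["lt_min_valid_alleles"] += 1
            continue
        max_len = max(abs(len(site.ref) - len(a)) for a in site.alts)
        out.append(MultiAllelicMarker(site, spectrum, n_valid, max_len))
        counts["kept"] += 1
    return out


def allele_count_histogram(markers: Sequence) -> dict[int, int]:
    """Histogram of the number of valid alleles per marker."""
    return dict(sorted(Counter(int(m.n_valid_alleles)
                               for m in markers).items()))


def allele_rank_summaries(markers: Sequence,
                          max_rank: int = 6) -> dict[int, dict[str, float]]:
    """Per-rank min/median/max global frequency over markers with that rank.

    Ranks beyond ``max_rank`` are pooled into an ``others`` bucket keyed 0,
    mirroring the alleles-1..6 reporting convention.
    """
    per_rank: dict[int, list[float]] = {}
    for m in markers:
        for rank, _allele, freq in m.spectrum.by_rank():
            key = rank if rank <= max_rank else 0
            per_rank.setdefault(key, []).append(freq)
    return {
        r: {"min": float(np.min(v)), "median": float(np.median(v)),
            "max": float(np.max(v)), "mean": float(np.mean(v)),
            "n": len(v)}
        for r, v in sorted(per_rank.items())
    }
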