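"""Multi-InDel construction: adjacency distances, the mean-difference
statistic behind the 20-bp gap threshold, clustering, and haplotype spectra.

The distance between two neighbouring indel sites is the number of reference
bases strictly between the REF span of the upstream site and the start of
the downstream site: ``pos_down - (pos_up + len(ref_up) - 1) - 1``.
Insertions occupy only their anchor base on the reference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import IndelSite, Panel, POPULATIONS
from .mai_filter import AlleleSpectrum, FilterParams


def pair_distance(upstream: IndelSite, downstream: IndelSite) -> int:
    """Reference bases strictly between two sites' REF spans (may be <= 0
    when spans touch or overlap)."""
    return downstream.pos - upstream.ref_end - 1


@dataclass
class DistanceHistogram:
    counts: dict[int, int] = field(default_factory=dict)

    def add(self, distance: int) -> None:
        self.counts[distance] = self.counts.get(distance, 0) + 1

    def get(self, distance: int) -> int:
        return self.counts.get(distance, 0)

    def max_distance(self) -> int:
        return max(self.counts) if self.counts else 0


def adjacent_distance_histogram(
    sites_by_chrom: dict[str, Sequence[IndelSite]] | Sequence[IndelSite],
) -> DistanceHistogram:
    """Distances between consecutive qualifying indel sites per chromosome.

    Accepts either a per-chromosome mapping or a flat sorted sequence (which
    is grouped by chromosome internally).  Only the sites the caller passes
    in are counted, so any randomness filtering happens upstream.
    """
    if not isinstance(sites_by_chrom, dict):
        grouped: dict[str, list[IndelSite]] = {}
        for s in sites_by_chrom:
            grouped.setdefault(s.chrom, []).append(s)
        sites_by_chrom = grouped
    hist = DistanceHistogram()
    for chrom, sites in sites_by_chrom.items():
        ordered = sorted(sites, key=lambda s: s.pos)
        for up, down in zip(ordered, ordered[1:]):
            hist.add(pair_distance(up, down))
    return hist


def mean_difference_series(
    hist: DistanceHistogram,
    s_max: int | None = None,
) -> dict[int, float]:
    """MDV(s) = (N[s-2]+N[s-1])/2 - (N[s+1]+N[s+2])/2 for s = 1..s_max.

    Distances absent from the histogram count as zero.
    """
    if s_max is None:
        s_max = hist.max_distance()
    out: dict[int, float] = {}
    for s in range(1, s_max + 1):
        left = (hist.get(s - 2) + hist.get(s - 1)) / 2.0
        right = (hist.get(s + 1) + hist.get(s + 2)) / 2.0
        out[s] = left - right
    return out


def suggest_gap_threshold(mdv: dict[int, float], cutoff: float = 25.0,
                          start: int = 3) -> int:
    """Largest s with MDV(s') > cutoff for every s' from ``start`` to s.

    The scan starts at s = 3 by default: for smaller s the left averaging
    window reaches below the smallest possible distance (1 bp), where counts
    are identically zero and the statistic is meaninglessly negative.
    Returns 0 when already s = start fails the cutoff.
    """
    s = start - 1
    while mdv.get(s + 1, float("-inf")) > cutoff:
        s += 1
    return 0 if s < start else s


def cluster_indels(
    sites: Sequence[IndelSite],
    max_gap: int = 20,
    mode: str = "consecutive_gap",
) -> list[list[IndelSite]]:
    """Group sorted same-chromosome sites into clusters of >= 2 members.

    ``consecutive_gap`` (default): single-linkage chaining, every
    consecutive distance <= max_gap.  ``span``: greedy left-to-right maximal
    clusters additionally requiring the distance between the first and last
    member <= max_gap.  Singletons are discarded.
    """
    if mode not in ("consecutive_gap", "span"):
        raise ValueError(f"unknown cluster mode {mode!r}")
    out: list[list[IndelSite]] = []
    by_chrom: dict[str, list[IndelSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in by_chrom:
        ordered = sorted(by_chrom[chrom], key=lambda s: s.pos)
        if mode == "consecutive_gap":
            cur = [ordered[0]]
            for s in ordered[1:]:
                if pair_distance(cur[-1], s) <= max_gap:
                    cur.append(s)
                else:
                    if len(cur) >= 2:
                        out.append(cur)
                    cur = [s]
            if len(cur) >= 2:
                out.append(cur)
        else:  # span: greedy maximal from the left
            i = 0
            n = len(ordered)
            while i < n:
                j = i
                while (j + 1 < n
                       and pair_distance(ordered[j], ordered[j + 1]) <= max_gap
                       and pair_distance(ordered[i], ordered[j + 1]) <= max_gap):
                    j += 1
                if j > i:
                    out.append(ordered[i:j + 1])
                i = j + 1
    return out


@dataclass
class MultiIndelMarker:
    member_sites: list[IndelSite]
    gaps: list[int]
    span: int
    spectrum: AlleleSpectrum
    n_valid_alleles: int

    @property
    def marker_id(self) -> str:
        return self.spectrum.marker_id

    @property
    def chrom(self) -> str:
        return self.member_sites[0].chrom

    @property
    def pos(self) -> int:
        """Anchor: position of the first member (1-based)."""
        return self.member_sites[0].pos

    def valid_allele_keys(self, params: FilterParams) -> list[str]:
        return [a for a, f in zip(self.spectrum.alleles, self.spectrum.global_freq)
                if params.is_valid(f)]


def haplotype_spectrum(cluster: Sequence[IndelSite], panel: Panel,
                       marker_id: str | None = None) -> AlleleSpectrum:
    """Phase-derived allele spectrum of a cluster.

    Each of the 2N haplotypes yields a key joining its member-site allele
    indices ("0-1", "1-0", ...); haplotypes missing at any member are
    dropped from all denominators.
    """
    gts = np.stack([s.genotypes for s in cluster], axis=-1)  # (n, 2, m)
    ok = (gts >= 0).all(axis=-1)                             # (n, 2)
    if not ok.any():
        raise ValueError("no complete haplotypes across cluster members")
    flat = gts.reshape(-1, gts.shape[-1])
    okflat = ok.reshape(-1)
    keys = np.array(["-".join(map(str, row)) for row in flat])
    observed = sorted(set(keys[okflat]))
    index = {k: i for i, k in enumerate(observed)}
    codes = np.array([index.get(k, -1) for k in keys]).reshape(gts.shape[:2])
    codes[~ok] = -1
    counts = np.bincount(codes[codes >= 0].ravel(), minlength=len(observed))
    pop_freq: dict[str, np.ndarray] = {}
    for pop in POPULATIONS:
        m = panel.pop_mask(pop)
        sub = codes[m]
        v = sub >= 0
        denom = int(v.sum())
        pop_freq[pop] = (np.bincount(sub[v].ravel(), minlength=len(observed))
                         / denom if denom else np.full(len(observed), np.nan))
    first = cluster[0]
    mid = marker_id or f"{first.chrom}:{first.pos}:mindel"
    return AlleleSpectrum(mid, observed, counts / counts.sum(),
                          pop_freq).nominate()


def filter_multi_indels(
    clusters: Iterable[Sequence[IndelSite]],
    panel: Panel,
    params: FilterParams | None = None,
    funnel: dict | None = None,
) -> list[MultiIndelMarker]:
    """Keep clusters whose haplotype spectrum has >= min_valid_alleles
    alleles above the frequency threshold."""
    params = params or FilterParams()
    counts = funnel if funnel is not None else {}
    for key in ("clusters", "lt_min_valid_alleles", "kept"):
        counts.setdefault(key, 0)
    out: list[MultiIndelMarker] = []
    for cluster in clusters:
        counts["clusters"] += 1
        spectrum = haplotype_spectrum(cluster, panel)
        n_valid = int(sum(bool(params.is_valid(f))
                          for f in spectrum.global_freq))
        if n_valid < params.min_valid_alleles:
            counts["lt_min_valid_alleles"] += 1
            continue
        gaps = [pair_distance(a, b) for a, b in zip(cluster, cluster[1:])]
        span = cluster[-1].ref_end - cluster[0].pos + 1
        out.append(MultiIndelMarker(list(cluster), gaps, span, spectrum, n_valid))
        counts["kept"] += 1
    return out
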