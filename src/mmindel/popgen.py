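"""Cross-population characterization of MM-InDel markers.

A marker is *present* in a superpopulation when at least
``min_valid_alleles`` of its alleles exceed the frequency threshold within
that population.  Markers present in all five populations are split into
ENTIRE_ALLELES (every globally valid allele is valid in every population)
versus LOSS_OR_BIRTH.  Alleles valid in exactly one population are that
population's specific alleles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import POPULATIONS
from .mai_filter import FilterParams


class PresenceCategory(str, Enum):
    ENTIRE_ALLELES = "ENTIRE_ALLELES"
    LOSS_OR_BIRTH = "LOSS_OR_BIRTH"


@dataclass
class PopulationPresence:
    marker_id: str
    present_in: frozenset
    allele_validity: dict[str, dict[str, bool]]  # allele -> pop -> valid
    category: PresenceCategory | None
    specific_alleles: dict[str, str] = field(default_factory=dict)


def _marker_allele_indices(marker) -> list[int]:
    site = getattr(marker, "site", None)
    if site is not None:
        return [0] + site.indel_alt_indices()
    return list(range(len(marker.spectrum.alleles)))


def population_presence(
    marker,
    params: FilterParams | None = None,
) -> PopulationPresence:
    """Presence, entire-vs-loss/birth category and population-specific
    alleles of one marker (multi-allelic or multi-InDel)."""
    params = params or FilterParams()
    spec = marker.spectrum
    idx = _marker_allele_indices(marker)
    alleles = [spec.alleles[i] for i in idx]
    globally_valid = [spec.alleles[i] for i in idx
                      if params.is_valid(spec.global_freq[i])]

    validity: dict[str, dict[str, bool]] = {a: {} for a in alleles}
    present = set()
    for pop in POPULATIONS:
        freqs = spec.pop_freq[pop]
        n_valid = 0
        for i, a in zip(idx, alleles):
            f = freqs[i]
            ok = bool(not np.isnan(f) and params.is_valid(f))
            validity[a][pop] = ok
            n_valid += ok
        if n_valid >= params.min_valid_alleles:
            present.add(pop)

    category = None
    if len(present) == len(POPULATIONS):
        entire = all(all(validity[a].values()) for a in globally_valid)
        category = (PresenceCategory.ENTIRE_ALLELES if entire
                    else PresenceCategory.LOSS_OR_BIRTH)

    specific = {}
    for a in alleles:
        pops = [p for p, ok in validity[a].items() if ok]
        if len(pops) == 1:
            specific[a] = pops[0]

    return PopulationPresence(marker.marker_id, frozenset(present),
                              validity, category, specific)


def intersection_counts(
    presences: Sequence[PopulationPresence],
) -> dict[frozenset, int]:
    """Venn-cell counts for all 31 non-empty population subsets."""
    cells = Counter(p.present_in for p in presences if p.present_in)
    # materialize every non-empty subset so downstream tables are complete
    from itertools import combinations
    out: dict[frozenset, int] = {}
    for k in range(1, len(POPULATIONS) + 1):
        for combo in combinations(POPULATIONS, k):
            out[frozenset(combo)] = cells.get(frozenset(combo), 0)
    return out


def venn_cells_json(counts: dict[frozenset, int]) -> dict[str, int]:
    return {"+".join(sorted(k)): v for k, v in sorted(
        counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))}


def presence_summary(presences: Sequence[PopulationPresence]) -> dict:
    """Headline shares: all-population markers, entire-allele fraction,
    single-population-specific alleles (both denominators emitted)."""
    n = len(presences)
    all_pop = [p for p in presences if len(p.present_in) == len(POPULATIONS)]
    entire = sum(p.category == PresenceCategory.ENTIRE_ALLELES for p in all_pop)
    with_specific = [p for p in presences if p.specific_alleles]
    specific_by_pop = Counter(pop for p in presences
                              for pop in p.specific_alleles.values())
    return {
        "n_markers": n,
        "n_all_populations": len(all_pop),
        "n_entire_alleles": entire,
        "n_loss_or_birth": len(all_pop) - entire,
        "fraction_entire_of_shared": entire / len(all_pop) if all_pop else np.nan,
        "n_with_specific_allele": len(with_specific),
        "fraction_specific_of_all": len(with_specific) / n if n else np.nan,
        "fraction_specific_of_shared": (
            sum(len(p.present_in) == len(POPULATIONS) for p in with_specific)
            / len(all_pop) if all_pop else np.nan),
        "specific_alleles_by_population": dict(specific_by_pop),
    }


def rank_frequency_by_population(markers: Sequence,
                                 max_rank: int = 6) -> pd.DataFrame:
    """Per-population mean frequency of alleles at global ranks 1..max_rank.

    Ranks are fixed by global nomination; the per-population mean at a rank
    averages over the markers where that rank exists, skipping populations
    with no usable haplotypes there.
    """
    acc: dict[tuple[int, str], list[float]] = {}
    for m in markers:
        spec = m.spectrum
        for rank, allele, _f in spec.by_rank():
            if rank > max_rank:
                continue
            i = spec.alleles.index(allele)
            for pop in POPULATIONS:
                f = spec.pop_freq[pop][i]
                if not np.isnan(f):
                    acc.setdefault((rank, pop), []).append(float(f))
    rows = []
    for rank in range(1, max_rank + 1):
        row: dict = {"rank": rank}
        for pop in POPULATIONS:
            v = acc.get((rank, pop))
            row[pop] = float(np.mean(v)) if v else np.nan
            row[f"n_{pop}"] = len(v) if v else 0
        rows.append(row)
    return pd.DataFrame(rows)
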