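"""100-kb binned genome scan: marker densities, GC content, recombination
rate, correlations, and density-group summaries.

Bins are 0-based half-open tiles; a variant with 1-based position p falls in
the bin containing 0-based coordinate p - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneticMapSegment


class Factor(str, Enum):
    SNP_DENSITY = "SNP_DENSITY"
    INDEL_DENSITY = "INDEL_DENSITY"
    GC = "GC"
    RC = "RC"


@dataclass
class GenomeBin:
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    n_mm: int = 0
    n_snp: int = 0
    n_indel: int = 0
    gc: float = float("nan")
    rc: float = float("nan")
    n_mask: int = 0


def make_bins(chrom_lengths: Mapping[str, int],
              width: int = 100_000) -> list[GenomeBin]:
    """Half-open tiling of every chromosome; the last bin is truncated."""
    bins: list[GenomeBin] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        for start in range(0, length, width):
            bins.append(GenomeBin(chrom, start, min(start + width, length)))
    return bins


def _bin_index(bins: Sequence[GenomeBin]) -> dict[str, list[GenomeBin]]:
    idx: dict[str, list[GenomeBin]] = {}
    for b in bins:
        idx.setdefault(b.chrom, []).append(b)
    for v in idx.values():
        v.sort(key=lambda b: b.start)
    return idx


def assign_counts(
    items: Iterable[tuple[str, int]],
    bins: Sequence[GenomeBin],
    attr: str,
    width: int = 100_000,
) -> None:
    """Count items (chrom, 1-based pos) into ``attr`` of their bins.

    Multi-part markers are anchored by the caller at their first member's
    position.  An item beyond the chromosome tiling is a hard error.
    """
    idx = _bin_index(bins)
    for chrom, pos in items:
        rows = idx.get(chrom)
        if rows is None:
            raise ValueError(f"item on untiled chromosome {chrom}")
        b = rows[min((pos - 1) // width, len(rows) - 1)]
        if not (b.start <= pos - 1 < b.end):
            raise ValueError(f"position {chrom}:{pos} beyond chromosome end")
        setattr(b, attr, getattr(b, attr) + 1)


def gc_content(reference: Mapping[str, str], b: GenomeBin) -> float:
    """(G+C)/(A+C+G+T) over the bin; N excluded; NaN when all N."""
    seq = reference[b.chrom][b.start:b.end]
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    b.n_mask = len(seq) - gc - at
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def mean_recombination_rate(segments: Sequence[GeneticMapSegment],
                            b: GenomeBin) -> float:
    """Length-weighted mean rate over the map's overlap with the bin.

    Bases not covered by the map carry no weight; NaN when nothing overlaps.
    """
    total_bp = 0
    acc = 0.0
    for seg in segments:
        if seg.chrom != b.chrom:
            continue
        # segment 1-based inclusive -> 0-based half-open
        s0, s1 = seg.start_pos - 1, seg.end_pos
        lo, hi = max(s0, b.start), min(s1, b.end)
        if lo < hi:
            total_bp += hi - lo
            acc += seg.rate * (hi - lo)
    return acc / total_bp if total_bp else float("nan")


def annotate_bins(
    bins: Sequence[GenomeBin],
    reference: Mapping[str, str] | None = None,
    map_segments: Sequence[GeneticMapSegment] | None = None,
) -> None:
    segs_by_chrom: dict[str, list[GeneticMapSegment]] = {}
    for seg in map_segments or ():
        segs_by_chrom.setdefault(seg.chrom, []).append(seg)
    for b in bins:
        if reference is not None and b.chrom in reference:
            b.gc = gc_content(reference, b)
        if map_segments is not None:
            b.rc = mean_recombination_rate(segs_by_chrom.get(b.chrom, ()), b)


@dataclass
class CorrelationResult:
    factor: Factor
    r: float
    p: float
    n_bins: int


_FACTOR_VALUES = {
    Factor.SNP_DENSITY: lambda b: float(b.n_snp),
    Factor.INDEL_DENSITY: lambda b: float(b.n_indel),
    Factor.GC: lambda b: b.gc,
    Factor.RC: lambda b: b.rc,
}


def correlate(bins: Sequence[GenomeBin], factor: Factor) -> CorrelationResult:
    """Pearson correlation of per-bin MM-InDel count with one factor.

    Bins with an undefined factor value are excluded pairwise.  Degenerate
    variance yields r = NaN.
    """
    x, y = [], []
    get = _FACTOR_VALUES[Factor(factor)]
    for b in bins:
        v = get(b)
        if not np.isnan(v):
            x.append(float(b.n_mm))
            y.append(v)
    if len(x) < 3:
        raise ValueError("need >= 3 bins with defined values")
    x, y = np.asarray(x), np.asarray(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(Factor(factor), float("nan"), float("nan"),
                                 len(x))
    res = stats.pearsonr(x, y)
    return CorrelationResult(Factor(factor), float(res.statistic),
                             float(res.pvalue), len(x))


DENSITY_GROUPS = ((0, 0, "0"), (1, 3, "1-3"), (4, None, ">3"))


def _mean_defined(values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def density_group_summary(bins: Sequence[GenomeBin]) -> pd.DataFrame:
    """Mean of each factor within MM-InDel density groups {0, 1-3, >3}."""
    rows = []
    for lo, hi, label in DENSITY_GROUPS:
        sel = [b for b in bins
               if b.n_mm >= lo and (hi is None or b.n_mm <= hi)]
        rows.append({
            "group": label,
            "n_bins": len(sel),
            "mean_snp": _mean_defined([float(b.n_snp) for b in sel]),
            "mean_indel": _mean_defined([float(b.n_indel) for b in sel]),
            "mean_gc": _mean_defined([b.gc for b in sel]),
            "mean_rc": _mean_defined([b.rc for b in sel]),
        })
    return pd.DataFrame(rows)


def fraction_empty(bins: Sequence[GenomeBin], denominator: str = "all") -> float:
    """Fraction of bins with no MM-InDel (``denominator``: all | non_n).

    ``non_n`` restricts the denominator to bins with defined GC (some
    non-N reference).
    """
    if denominator == "non_n":
        pool = [b for b in bins if not np.isnan(b.gc)]
    else:
        pool = list(bins)
    if not pool:
        raise ValueError("no bins")
    return sum(b.n_mm == 0 for b in pool) / len(pool)


def bins_to_frame(bins: Sequence[GenomeBin]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": b.chrom, "start": b.start, "end": b.end, "n_mm": b.n_mm,
        "n_snp": b.n_snp, "n_indel": b.n_indel, "gc": b.gc, "rc": b.rc,
        "n_mask": b.n_mask,
    } for b in bins])
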