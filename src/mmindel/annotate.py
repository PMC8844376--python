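"""Genomic-context classification of markers against repeat elements and
gene models."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import AnnotationInterval, FeatureKind


class RepeatClass(str, Enum):
    SINE = "SINE"
    LINE = "LINE"
    LTR = "LTR"
    OTHER_REPEAT = "OTHER_REPEAT"
    NONE = "NONE"


class GeneContext(str, Enum):
    CDS = "CDS"
    EXON_NONCODING = "EXON_NONCODING"
    INTRON = "INTRON"
    INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class MarkerAnnotation:
    marker_id: str
    repeat_class: RepeatClass
    gene_context: GeneContext


class AnnotationIndex:
    """Per-chromosome interval trees over repeat and gene features."""

    def __init__(self, repeats: Iterable[AnnotationInterval],
                 genes: Iterable[AnnotationInterval]):
        self._repeat: dict[str, IntervalTree] = {}
        self._gene: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        self._cds: dict[str, IntervalTree] = {}
        for iv in repeats:
            self._repeat.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv.kind)
        for iv in genes:
            target = {FeatureKind.GENE: self._gene,
                      FeatureKind.EXON: self._exon,
                      FeatureKind.CDS: self._cds}.get(iv.kind)
            if target is not None:
                target.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, iv.kind)

    @staticmethod
    def _hits(trees: dict[str, IntervalTree], chrom: str,
              start: int, end: int):
        t = trees.get(chrom)
        return list(t.overlap(start, end)) if t is not None else []

    def annotate_point(self, marker_id: str, chrom: str, point0: int,
                       span_end0: int | None = None) -> MarkerAnnotation:
        """Classify an anchor point (0-based); with ``span_end0`` given the
        whole span [point0, span_end0) is tested instead (any-overlap)."""
        end = span_end0 if span_end0 is not None else point0 + 1
        rep_hits = self._hits(self._repeat, chrom, point0, end)
        if rep_hits:
            # class of the containing/overlapping repeat with longest overlap
            def overlap(iv):
                return min(iv.end, end) - max(iv.begin, point0)
            best = max(rep_hits, key=lambda iv: (overlap(iv), -iv.begin))
            repeat = RepeatClass(best.data.value) if best.data in (
                FeatureKind.SINE, FeatureKind.LINE, FeatureKind.LTR
            ) else RepeatClass.OTHER_REPEAT
        else:
            repeat = RepeatClass.NONE
        if self._hits(self._cds, chrom, point0, end):
            gene = GeneContext.CDS
        elif self._hits(self._exon, chrom, point0, end):
            gene = GeneContext.EXON_NONCODING
        elif self._hits(self._gene, chrom, point0, end):
            gene = GeneContext.INTRON
        else:
            gene = GeneContext.INTERGENIC
        return MarkerAnnotation(marker_id, repeat, gene)


def annotate_marker(marker, index: AnnotationIndex,
                    use_span: bool = False) -> MarkerAnnotation:
    """Annotate a MultiAllelicMarker or MultiIndelMarker by its anchor point
    (normalized start, 0-based), or by its whole span with ``use_span``."""
    site = getattr(marker, "site", None)
    if site is not None:  # multi-allelic marker
        chrom, pos = site.chrom, site.pos
        end = site.ref_end
    else:  # multi-indel marker
        chrom, pos = marker.chrom, marker.pos
        end = marker.member_sites[-1].ref_end
    if use_span:
        return index.annotate_point(marker.marker_id, chrom, pos - 1, end)
    return index.annotate_point(marker.marker_id, chrom, pos - 1)


def annotation_summary(annotations: Sequence[MarkerAnnotation]) -> dict:
    """Counts and fractions per repeat class and gene context."""
    n = len(annotations)
    rep = Counter(a.repeat_class.value for a in annotations)
    gene = Counter(a.gene_context.value for a in annotations)
    in_repeat = sum(v for k, v in rep.items() if k != "NONE")
    in_gene = sum(v for k, v in gene.items() if k != "INTERGENIC")
    return {
        "n_markers": n,
        "repeat_counts": dict(rep),
        "gene_counts": dict(gene),
        "fraction_in_repeat": in_repeat / n if n else 0.0,
        "fraction_in_gene": in_gene / n if n else 0.0,
    }
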