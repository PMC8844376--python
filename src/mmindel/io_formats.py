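"""Readers/writers for the external formats the pipeline touches, and the
internal variant data model.

Coordinate conventions
----------------------
Variant positions (:class:`IndelSite.pos`) are 1-based, VCF style, pointing at
the first REF base.  Genome bins and annotation intervals are 0-based
half-open (BED style).  Genetic-map segments use 1-based inclusive bounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

POPULATIONS = ("AFR", "AMR", "EUR", "EAS", "SAS")

_DNA = re.compile(r"^[ACGT]+$")

AUTOSOMES = {str(i) for i in range(1, 23)}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix: 'chr1' and '1' both become '1'."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


class VariantKind(str, Enum):
    INS = "INS"
    DEL = "DEL"
    SNP = "SNP"
    OTHER = "OTHER"


class FeatureKind(str, Enum):
    SINE = "SINE"
    LINE = "LINE"
    LTR = "LTR"
    OTHER_REPEAT = "OTHER_REPEAT"
    GENE = "GENE"
    EXON = "EXON"
    CDS = "CDS"


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    population: str

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(
                f"unknown population {self.population!r} for sample "
                f"{self.sample_id!r}; expected one of {POPULATIONS}"
            )


class Panel:
    """Sample -> superpopulation table with per-population index masks."""

    def __init__(self, samples: Sequence[SampleInfo]):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in panel")
        self.samples = list(samples)
        self.sample_ids = ids
        self.index = {sid: i for i, sid in enumerate(ids)}
        self._pop_masks = {
            pop: np.array([s.population == pop for s in samples], dtype=bool)
            for pop in POPULATIONS
        }

    def __len__(self) -> int:
        return len(self.samples)

    def pop_mask(self, pop: str) -> np.ndarray:
        return self._pop_masks[pop]

    def pop_sizes(self) -> dict[str, int]:
        return {pop: int(m.sum()) for pop, m in self._pop_masks.items()}

    @classmethod
    def read(cls, path: str | Path) -> "Panel":
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        sid = cols.get("sample_id", cols.get("sample"))
        pop = cols.get("population", cols.get("pop"))
        if sid is None or pop is None:
            raise ValueError(f"panel {path} lacks sample_id/population columns")
        return cls([SampleInfo(str(r[sid]), str(r[pop])) for _, r in df.iterrows()])

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": self.sample_ids,
             "population": [s.population for s in self.samples]}
        ).to_csv(path, sep="\t", index=False)


def classify_alt(ref: str, alt: str) -> VariantKind:
    if len(alt) > len(ref):
        return VariantKind.INS
    if len(alt) < len(ref):
        return VariantKind.DEL
    if len(ref) == 1:
        return VariantKind.SNP
    diffs = sum(a != b for a, b in zip(ref, alt))
    return VariantKind.SNP if diffs == 1 else VariantKind.OTHER


@dataclass
class IndelSite:
    """A left-normalized, possibly multi-allelic variant site.

    ``genotypes`` is an ``(n_samples, 2)`` int16 array of allele indices into
    ``[ref] + alts`` (phased: column 0 = first haplotype); -1 marks missing.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    genotypes: np.ndarray
    kinds: list[VariantKind] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.kinds:
            self.kinds = [classify_alt(self.ref, a) for a in self.alts]

    @property
    def alleles(self) -> list[str]:
        return [self.ref] + list(self.alts)

    @property
    def ref_end(self) -> int:
        """1-based position of the last REF base."""
        return self.pos + len(self.ref) - 1

    @property
    def n_indel_alts(self) -> int:
        return sum(k in (VariantKind.INS, VariantKind.DEL) for k in self.kinds)

    def indel_alt_indices(self) -> list[int]:
        """Allele indices (into ``alleles``) of the insertion/deletion alts."""
        return [i + 1 for i, k in enumerate(self.kinds)
                if k in (VariantKind.INS, VariantKind.DEL)]

    def atoms(self) -> list[tuple[int, str, str, VariantKind]]:
        """Minimal per-alt representations ``(pos, ref, alt, kind)``.

        Shared suffix then shared prefix are trimmed, keeping one anchor base
        when an allele would otherwise become empty (VCF convention).
        """
        out = []
        for alt, kind in zip(self.alts, self.kinds):
            p, r, a = _trim(self.pos, self.ref, alt)
            out.append((p, r, a, kind))
        return out


@dataclass(frozen=True)
class GeneticMapSegment:
    chrom: str
    start_pos: int  # 1-based inclusive
    end_pos: int    # 1-based inclusive
    rate: float     # cM/Mb

    def __post_init__(self) -> None:
        if self.start_pos >= self.end_pos:
            raise ValueError("genetic-map segment start must precede end")
        if self.rate < 0:
            raise ValueError("negative recombination rate")


@dataclass(frozen=True)
class AnnotationInterval:
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    kind: FeatureKind
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty annotation interval")


# ---------------------------------------------------------------------------
# variant normalization


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # shared suffix first, then shared prefix; keep >=1 base in each allele
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str],
) -> tuple[int, str, str]:
    """Left-align and parsimony-trim one variant (1-based ``pos``).

    ``reference`` maps chromosome name -> sequence string.  Raises
    ``ValueError`` if ``ref`` does not match the reference or the alleles are
    identical.
    """
    seq = reference[chrom]
    if ref != seq[pos - 1: pos - 1 + len(ref)]:
        raise ValueError(
            f"REF mismatch at {chrom}:{pos}: VCF says {ref!r}, "
            f"reference has {seq[pos - 1: pos - 1 + len(ref)]!r}"
        )
    if ref == alt:
        raise ValueError(f"not a variant at {chrom}:{pos}: REF == ALT {ref!r}")
    pos, ref, alt = _trim(pos, ref, alt)
    # left shift: while both alleles end with the same base, roll that base
    # off the end and pull the preceding reference base onto the front
    while pos > 1 and ref[-1] == alt[-1]:
        prev = seq[pos - 2]
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
        pos, ref, alt = _trim(pos, ref, alt)
    return pos, ref, alt


# ---------------------------------------------------------------------------
# phased VCF reading


class _Atom:
    """One biallelic alt in normalized form plus its haplotype masks."""

    __slots__ = ("pos", "ref", "alt", "carriers", "missing")

    def __init__(self, pos: int, ref: str, alt: str,
                 carriers: np.ndarray, missing: np.ndarray):
        self.pos, self.ref, self.alt = pos, ref, alt
        self.carriers = carriers  # (n_samples, 2) bool: haplotype has this alt
        self.missing = missing    # (n_samples, 2) bool: GT unknown/unphased


def _merge_atoms(chrom: str, pos: int, atoms: list[_Atom],
                 n_samples: int) -> IndelSite:
    """Merge biallelic atoms at one normalized position into one site.

    Alts are re-expressed against the longest REF by appending the reference
    suffix the shorter REFs do not cover, then deduplicated and ordered by
    (length, sequence) for determinism.  A haplotype that is missing in any
    contributing record, or that carries two different atoms at the locus,
    is set missing in the merged genotypes.
    """
    ref = max((a.ref for a in atoms), key=len)
    by_alt: dict[str, list[_Atom]] = {}
    for a in atoms:
        ext = a.alt + ref[len(a.ref):]
        if ext == ref:  # degenerate after extension
            continue
        by_alt.setdefault(ext, []).append(a)
    alts = sorted(by_alt, key=lambda s: (len(s), s))
    gt = np.zeros((n_samples, 2), dtype=np.int16)
    claimed = np.zeros((n_samples, 2), dtype=bool)
    conflict = np.zeros((n_samples, 2), dtype=bool)
    missing = np.zeros((n_samples, 2), dtype=bool)
    for a in atoms:
        missing |= a.missing
    for idx, alt in enumerate(alts, start=1):
        carr = np.zeros((n_samples, 2), dtype=bool)
        for a in by_alt[alt]:
            carr |= a.carriers
        conflict |= claimed & carr
        gt[carr] = idx
        claimed |= carr
    gt[conflict | missing] = -1
    return IndelSite(chrom=chrom, pos=pos, ref=ref, alts=alts, genotypes=gt)


def read_phased_vcf(
    path: str | Path,
    panel: Panel,
    reference: Mapping[str, str] | None = None,
    autosomes_only: bool = True,
    strict: bool = False,
) -> Iterator[IndelSite]:
    """Stream normalized, merged :class:`IndelSite` records from a VCF.

    Biallelic records sharing one normalized position are merged into a
    single multi-allelic site.  With ``reference`` given, every alt is
    left-aligned; without it only parsimony trimming is applied.  Unphased or
    missing genotypes become missing haplotypes (-1); with ``strict`` they
    are a hard error instead.
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    for sid in panel.sample_ids:
        if sid not in vcf_samples:
            raise ValueError(f"panel sample {sid!r} missing from VCF {path}")
    order = [vcf_samples.index(sid) for sid in panel.sample_ids]
    n = len(panel)

    pending: dict[int, list[_Atom]] = {}
    pending_chrom: str | None = None
    # left alignment only moves positions down, and never by more than the
    # record span plus the shift window; flushing everything more than this
    # far behind the current raw position is safe
    flush_lag = 1000

    def flush(upto: int | None) -> Iterator[IndelSite]:
        for p in sorted(pending):
            if upto is None or p < upto:
                yield _merge_atoms(pending_chrom, p, pending.pop(p), n)

    for rec in vf:
        chrom = rec.chrom
        if autosomes_only and not is_autosome(chrom):
            continue
        if pending_chrom is not None and chrom != pending_chrom:
            yield from flush(None)
        pending_chrom = chrom
        yield from flush(rec.pos - flush_lag)

        missing = np.zeros((n, 2), dtype=bool)
        codes = np.full((n, 2), -1, dtype=np.int16)
        for i, oi in enumerate(order):
            smp = rec.samples[oi]
            gt = smp.get("GT")
            bad = gt is None or len(gt) != 2
            if not bad and not smp.phased and gt[0] != gt[1]:
                bad = True  # heterozygous but unphased: haplotypes unknown
            if bad:
                if strict:
                    raise ValueError(
                        f"missing/unphased GT for {panel.sample_ids[i]} at "
                        f"{chrom}:{rec.pos}")
                missing[i] = True
                continue
            for h in (0, 1):
                if gt[h] is None:  # one-sided missing haplotype
                    if strict:
                        raise ValueError(
                            f"missing GT for {panel.sample_ids[i]} at "
                            f"{chrom}:{rec.pos}")
                    missing[i, h] = True
                else:
                    codes[i, h] = gt[h]

        ref = rec.ref.upper()
        for ai, alt in enumerate(rec.alts or (), start=1):
            alt = alt.upper()
            if not _DNA.match(alt) or not _DNA.match(ref):
                continue  # symbolic/structural allele: out of scope
            if reference is not None:
                p, r, a = normalize_variant(chrom, rec.pos, ref, alt, reference)
            else:
                p, r, a = _trim(rec.pos, ref, alt)
            carriers = (codes == ai) & ~missing
            pending.setdefault(p, []).append(_Atom(p, r, a, carriers, missing))

    yield from flush(None)


def write_phased_vcf(
    sites: Iterable[IndelSite],
    panel: Panel,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Emit sites as plain-text VCF 4.2 with phased GT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for s in sites:
            gts = []
            for i in range(len(panel)):
                a, b = s.genotypes[i]
                gts.append(f"{a if a >= 0 else '.'}|{b if b >= 0 else '.'}")
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{','.join(s.alts)}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# genetic map


def read_genetic_map(path: str | Path) -> list[GeneticMapSegment]:
    """Parse HapMap-II style genetic-map text into rate segments.

    Accepts the 3-column per-chromosome layout (position, rate, cumulative cM)
    or a 4-column combined layout with a leading chromosome column.  Each pair
    of consecutive positions becomes one segment carrying the left endpoint's
    rate.  Non-monotone positions within a chromosome are a hard error.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = list(df.columns)
    if len(cols) >= 4:
        chroms = df[cols[0]].astype(str)
        pos = df[cols[1]].astype(int)
        rate = df[cols[2]].astype(float)
    elif len(cols) == 3:
        chroms = pd.Series(["?"] * len(df))
        pos = df[cols[0]].astype(int)
        rate = df[cols[1]].astype(float)
    else:
        raise ValueError(f"unrecognized genetic map layout in {path}")
    segments: list[GeneticMapSegment] = []
    for chrom, grp in df.assign(_c=chroms, _p=pos, _r=rate).groupby("_c", sort=False):
        p = grp["_p"].to_numpy()
        r = grp["_r"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"non-monotone positions in genetic map {path} "
                             f"chromosome {chrom}")
        for i in range(len(p) - 1):
            segments.append(GeneticMapSegment(str(chrom), int(p[i]),
                                              int(p[i + 1]) - 1, float(r[i])))
    return segments


# ---------------------------------------------------------------------------
# annotations

_REPEAT_KINDS = {"SINE": FeatureKind.SINE, "LINE": FeatureKind.LINE,
                 "LTR": FeatureKind.LTR}
_GFF_KINDS = {"gene": FeatureKind.GENE, "exon": FeatureKind.EXON,
              "CDS": FeatureKind.CDS, "mRNA": None}


def read_annotations(
    path: str | Path,
    unknown: str = "other",
) -> list[AnnotationInterval]:
    """Read BED (0-based half-open) or GFF3 (1-based, converted) intervals.

    BED column 5 (or 4 if only 4 columns) carries the feature kind.  Unknown
    kinds are recorded as OTHER_REPEAT (``unknown='other'``) or dropped
    (``unknown='skip'``).
    """
    path = Path(path)
    out: list[AnnotationInterval] = []
    if path.suffix.lower() in (".gff", ".gff3"):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                ftype = f[2]
                kind = _GFF_KINDS.get(ftype, "?")
                if kind is None:
                    continue
                if kind == "?":
                    if unknown == "skip":
                        continue
                    kind = FeatureKind.OTHER_REPEAT
                name = ""
                for kv in f[8].split(";"):
                    if kv.startswith("ID="):
                        name = kv[3:]
                out.append(AnnotationInterval(
                    f[0], int(f[3]) - 1, int(f[4]), kind, name))
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split()
                name = f[3] if len(f) > 3 else ""
                kind_str = f[4] if len(f) > 4 else (f[3] if len(f) > 3 else "")
                kind = _REPEAT_KINDS.get(kind_str.upper())
                if kind is None:
                    if unknown == "skip":
                        continue
                    kind = FeatureKind.OTHER_REPEAT
                out.append(AnnotationInterval(
                    f[0], int(f[1]), int(f[2]), kind, name))
    return out


# ---------------------------------------------------------------------------
# marker tables

MARKER_TABLE_COLUMNS = [
    "marker_id", "chrom", "start", "end", "type", "n_alleles",
    "allele_seqs", "global_freqs", "pop_freqs", "annotation_class",
]


def write_marker_table(rows: Iterable[dict], path: str | Path) -> None:
    df = pd.DataFrame(list(rows))
    for col in MARKER_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[MARKER_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# FASTA helpers


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA into a plain dict of upper-case strings."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
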