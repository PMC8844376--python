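"""Random-sequence classification of indel alleles and their flanks.

An insertion/deletion allele is called *random* when it is not an expansion
of a monomeric base or of a 2-15 bp tandem-repeat unit.  "Expansion" is read
mechanistically: the indel sequence S must sit inside a perfect tandem array
(two or more full adjacent copies of one unit) formed by S together with its
reference flanks.  A pure array S = u^k with k >= 2 therefore qualifies
unconditionally, while a single-copy sequence counts only when the flanking
reference completes the array across the junction (the slippage situation).

Flank randomness is a separate test on the 12 bp of reference on either side
of the variant: a flank fails when it carries a long homopolymer run or a
perfect 2-15 bp tandem array of sufficient length, both thresholds
configurable in :class:`ClassParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .io_formats import IndelSite, VariantKind

_ACGT = set("ACGT")


@dataclass(frozen=True)
class ClassParams:
    """Tunable thresholds for the random-sequence decision (all in bp)."""

    min_unit: int = 1
    max_unit: int = 15
    flank_len: int = 12
    flank_homopolymer_max: int = 5
    flank_array_min_len: int = 8
    flank_array_min_copies: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.min_unit <= self.max_unit):
            raise ValueError("require 1 <= min_unit <= max_unit")
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")


DEFAULT_PARAMS = ClassParams()


class Verdict(str, Enum):
    RANDOM = "RANDOM"
    MONOMERIC_EXPANSION = "MONOMERIC_EXPANSION"
    MULTIMER_EXPANSION = "MULTIMER_EXPANSION"
    FLANK_REPEAT = "FLANK_REPEAT"


@dataclass(frozen=True)
class SequenceClassification:
    verdict: Verdict
    unit: str = ""
    copies: int = 0


def smallest_period(seq: str) -> tuple[str, int]:
    """Shortest unit u and count k with ``seq == u * k`` (k >= 1)."""
    if not seq:
        raise ValueError("empty sequence has no period")
    n = len(seq)
    for p in range(1, n + 1):
        if n % p == 0 and seq == seq[:p] * (n // p):
            return seq[:p], n // p
    raise AssertionError("unreachable")  # p = n always matches


def _containing_array(T: str, a: int, b: int, q: int) -> tuple[str, int] | None:
    """Find a tandem array of unit length ``q`` with >= 2 full copies inside
    ``T`` whose span contains ``[a, b)``.  Returns (unit, copies) or None.

    Works on the q-shift match profile: a maximal stretch of positions i with
    ``T[i] == T[i+q]`` delimits the periodic region from which full-copy
    arrays can be cut.
    """
    n = len(T)
    if n < 2 * q:
        return None
    i = 0
    m = n - q
    while i < m:
        if T[i] != T[i + q]:
            i += 1
            continue
        j = i
        while j < m and T[j] == T[j + q]:
            j += 1
        t0, t1 = i, j  # matches on [t0, t1); periodic region [t0, t1 + q)
        if t0 <= a and t1 + q >= b and t1 - t0 >= q:
            for s0 in range(t0, min(a, t1 - q) + 1):
                c = (t1 + q - s0) // q
                if c >= 2 and s0 + c * q >= b:
                    return T[s0:s0 + q], c
        i = j
    return None


def classify_indel_sequence(
    S: str,
    L: str,
    R: str,
    params: ClassParams = DEFAULT_PARAMS,
) -> SequenceClassification:
    """Classify one indel sequence ``S`` given reference flanks ``L``/``R``.

    For deletions ``S`` is the deleted reference sequence and L/R flank the
    deleted span; for insertions L/R flank the insertion point.
    """
    if not S:
        raise ValueError("empty indel sequence")
    for part, label in ((S, "indel"), (L, "left flank"), (R, "right flank")):
        if set(part) - _ACGT:
            raise ValueError(f"non-ACGT base in {label} sequence {part!r}")

    if len(set(S)) == 1:
        b = S[0]
        if len(S) >= 2 or L.endswith(b) or R.startswith(b):
            return SequenceClassification(Verdict.MONOMERIC_EXPANSION, b, len(S))
        # a lone base can still sit inside a longer-unit array spanning the
        # junction (e.g. G between ..TA and CGCC.. completes GCGC)

    T = L + S + R
    a, b = len(L), len(L) + len(S)
    for q in range(max(2, params.min_unit), params.max_unit + 1):
        hit = _containing_array(T, a, b, q)
        if hit is not None:
            unit, copies = hit
            return SequenceClassification(Verdict.MULTIMER_EXPANSION, unit, copies)
    return SequenceClassification(Verdict.RANDOM)


def _flank_has_repeat(flank: str, params: ClassParams) -> bool:
    n = len(flank)
    # homopolymer run
    run = 1
    for i in range(1, n):
        run = run + 1 if flank[i] == flank[i - 1] else 1
        if run > params.flank_homopolymer_max:
            return True
    # perfect tandem array of a 2..max_unit unit
    for q in range(2, params.max_unit + 1):
        for s0 in range(0, n - 2 * q + 1):
            unit = flank[s0:s0 + q]
            c = 1
            while flank[s0 + c * q: s0 + (c + 1) * q] == unit:
                c += 1
            if c >= params.flank_array_min_copies and c * q >= params.flank_array_min_len:
                return True
    return False


def flank_is_random(L: str, R: str, params: ClassParams = DEFAULT_PARAMS) -> bool:
    """True iff neither flank carries a disqualifying homopolymer or array."""
    return not (_flank_has_repeat(L, params) or _flank_has_repeat(R, params))


def _atom_context(
    site: IndelSite,
    atom: tuple[int, str, str, VariantKind],
    reference: Mapping[str, str],
    params: ClassParams,
) -> tuple[str, str, str]:
    """(S, L, R) for one indel atom of a normalized site.

    Flanks shorter than ``flank_len`` at contig edges are used truncated.
    """
    pos, ref, alt, kind = atom
    seq = reference[site.chrom]
    if kind == VariantKind.DEL:
        S = ref[len(alt):] if ref.startswith(alt) else ref[1:]
        anchor_end = pos + len(alt) - 1 if ref.startswith(alt) else pos
        del_end = pos + len(ref) - 1  # last deleted base, 1-based
        L = seq[max(0, anchor_end - params.flank_len): anchor_end]
        R = seq[del_end: del_end + params.flank_len]
    elif kind == VariantKind.INS:
        S = alt[len(ref):] if alt.startswith(ref) else alt[1:]
        anchor_end = pos + len(ref) - 1
        L = seq[max(0, anchor_end - params.flank_len): anchor_end]
        R = seq[anchor_end: anchor_end + params.flank_len]
    else:
        raise ValueError("atom is not an indel")
    return S, L, R


def classify_site_alleles(
    site: IndelSite,
    reference: Mapping[str, str],
    params: ClassParams = DEFAULT_PARAMS,
) -> list[SequenceClassification]:
    """Classification of every indel alt at a site, in alt order.

    Non-indel alts get a RANDOM placeholder (they are not part of the indel
    allele set).  An allele whose own sequence is random but whose flank
    fails :func:`flank_is_random` is reported as FLANK_REPEAT.
    """
    out: list[SequenceClassification] = []
    for atom in site.atoms():
        kind = atom[3]
        if kind not in (VariantKind.INS, VariantKind.DEL):
            out.append(SequenceClassification(Verdict.RANDOM))
            continue
        S, L, R = _atom_context(site, atom, reference, params)
        cls = classify_indel_sequence(S, L, R, params)
        if cls.verdict == Verdict.RANDOM and not flank_is_random(L, R, params):
            cls = SequenceClassification(Verdict.FLANK_REPEAT)
        out.append(cls)
    return out


def site_is_random_context(
    site: IndelSite,
    reference: Mapping[str, str],
    params: ClassParams = DEFAULT_PARAMS,
) -> bool:
    """True iff every indel alt classifies RANDOM and its flank is random."""
    if site.chrom not in reference:
        raise ValueError(f"no reference sequence for {site.chrom}")
    verdicts = classify_site_alleles(site, reference, params)
    indel = [v for v, k in zip(verdicts, site.kinds)
             if k in (VariantKind.INS, VariantKind.DEL)]
    return bool(indel) and all(v.verdict == Verdict.RANDOM for v in indel)
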