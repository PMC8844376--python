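"""Synthetic phased-cohort generator with a machine-readable truth manifest.

Emits every input the pipeline consumes — a GC-heterogeneous reference
FASTA, a phased VCF for five superpopulation cohorts, a panel table, a
HapMap-II style genetic map, repeat BED and gene GFF3 — plus a JSON manifest
recording every planted variant, its sequence class, target and realized
allele frequencies, cluster structure, and the verdict the filter criteria
imply for it.

Haplotypes are sampled at the haplotype level (multinomial per locus, or per
joint haplotype table for clusters) so multi-locus spectra are exactly
controllable; diploids are formed by pairing haplotypes within population.
Sites are planted left-normalized and far enough apart (outside deliberate
clusters) that no unintended adjacency below the clustering gap can arise.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    IndelSite, Panel, SampleInfo, POPULATIONS, classify_alt,
    write_fasta, write_phased_vcf,
)
from .seq_class import (
    ClassParams, DEFAULT_PARAMS, Verdict, classify_indel_sequence,
    flank_is_random,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ScenarioSpec:
    """Composition of one synthetic cohort (the desk-scale study design).

    Counts are numbers of planted loci of each kind; frequencies are targets
    the realized (sampled) frequencies fluctuate around.
    """

    pop_sizes: dict = field(default_factory=lambda: {p: 40 for p in POPULATIONS})
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 5_000_000, "chr2": 5_000_000})
    chrx_length: int = 300_000
    gc_block_len: int = 1_000_000
    gc_levels: tuple = (0.35, 0.55)
    n_blocks: tuple = (("chr1", 2_400_000, 2_450_000),)
    min_sep: int = 60

    n_snp: int = 1100
    n_biallelic_indel: int = 420
    n_expansion_indel: int = 40
    n_ma_qualifying: int = 70
    n_ma_lowfreq: int = 25
    n_ma_expansion_allele: int = 20
    n_ma_flank_repeat: int = 20
    n_ma_with_snp_alt: int = 15
    n_ma_pop_specific: int = 12
    n_cluster_pair: int = 60
    n_cluster_triple: int = 15
    n_cluster_four_combo: int = 8
    n_cluster_linked: int = 10
    n_cluster_wide: int = 12
    n_cluster_ma_member: int = 5
    n_chrx_records: int = 10

    split_prob: float = 0.5
    af_min: float = 0.01
    max_gap: int = 20
    map_segment_len: int = 500_000
    n_repeats: int = 120
    n_genes: int = 30


def desk_preset() -> ScenarioSpec:
    """Default desk-scale scenario: 5 populations x 40 diploids, 2 autosomes
    x 5 Mb, ~2,000 planted variants; runs end to end in seconds."""
    return ScenarioSpec()


# ---------------------------------------------------------------------------
# reference


def generate_reference(spec: ScenarioSpec, rng: np.random.Generator,
                       ) -> dict[str, np.ndarray]:
    """I.i.d. reference with alternating GC blocks and optional N masks.

    Returns mutable uint8 arrays (ASCII) so expansions/flank arrays can be
    written in before the FASTA is emitted.
    """
    seqs: dict[str, np.ndarray] = {}
    lengths = dict(spec.chrom_lengths)
    if spec.chrx_length:
        lengths["chrX"] = spec.chrx_length
    for chrom, length in lengths.items():
        arr = np.empty(length, dtype=np.uint8)
        for start in range(0, length, spec.gc_block_len):
            end = min(start + spec.gc_block_len, length)
            gc = spec.gc_levels[(start // spec.gc_block_len) % len(spec.gc_levels)]
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            arr[start:end] = rng.choice(_BASES, size=end - start, p=p)
        seqs[chrom] = arr
    for chrom, s, e in spec.n_blocks:
        seqs[chrom][s:e] = ord("N")
    return seqs


def gc_of_block(spec: ScenarioSpec, pos: int) -> float:
    return spec.gc_levels[(pos // spec.gc_block_len) % len(spec.gc_levels)]


class _Placer:
    """Reserves non-overlapping anchor positions, GC-weighted so variant
    density tracks GC content."""

    def __init__(self, spec: ScenarioSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.reserved: dict[str, list[tuple[int, int]]] = {
            c: [] for c in spec.chrom_lengths}
        chroms = list(spec.chrom_lengths)
        w = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
        self._chroms, self._cw = chroms, w / w.sum()
        self._wmax = max(spec.gc_levels)

    def _free(self, chrom: str, start: int, end: int) -> bool:
        res = self.reserved[chrom]
        i = bisect_left(res, (start, start))
        for j in (i - 1, i):
            if 0 <= j < len(res):
                s, e = res[j]
                if s < end and start < e:
                    return False
        return True

    def place(self, span: int, gc_weighted: bool = True) -> tuple[str, int]:
        """Returns (chrom, 1-based anchor pos) with [pos-min_sep,
        pos+span+min_sep) reserved."""
        spec = self.spec
        for _ in range(5000):
            chrom = self._chroms[self.rng.choice(len(self._chroms), p=self._cw)]
            length = spec.chrom_lengths[chrom]
            pos = int(self.rng.integers(50, length - span - 50))
            if gc_weighted and self.rng.random() > gc_of_block(spec, pos) / self._wmax:
                continue
            start, end = pos - spec.min_sep, pos + span + spec.min_sep
            if not self._free(chrom, start, end):
                continue
            insort(self.reserved[chrom], (start, end))
            return chrom, pos + 1  # 1-based
        raise RuntimeError("could not place variant; scenario too dense")


# ---------------------------------------------------------------------------
# sequence helpers


def _decode(arr: np.ndarray, start0: int, end0: int) -> str:
    return arr[max(0, start0):end0].tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _indel_len(rng: np.random.Generator) -> int:
    return int(min(1 + rng.geometric(0.3), 25))


_PARAMS = DEFAULT_PARAMS


def _context(ref: np.ndarray, pos: int, ref_len: int,
             params: ClassParams = _PARAMS) -> tuple[str, str]:
    """Reference flanks (L, R) of a variant atom: L ends at the anchor base,
    R starts after the REF span.  1-based ``pos``."""
    anchor0 = pos - 1
    L = _decode(ref, anchor0 + 1 - params.flank_len, anchor0 + 1)
    R = _decode(ref, anchor0 + ref_len, anchor0 + ref_len + params.flank_len)
    return L, R


def _del_ok_random(ref: np.ndarray, pos: int, d: int) -> bool:
    """Deleting d bases after the anchor at ``pos`` is a random-class,
    normalization-stable deletion in a random flank."""
    anchor0 = pos - 1
    window = _decode(ref, anchor0, anchor0 + 1 + d)
    if "N" in window or len(window) < 1 + d:
        return False
    S = window[1:]
    if S[-1] == window[0]:  # left-shiftable: not normalization-stable
        return False
    L = _decode(ref, anchor0 + 1 - _PARAMS.flank_len, anchor0 + 1)
    R = _decode(ref, anchor0 + 1 + d, anchor0 + 1 + d + _PARAMS.flank_len)
    if "N" in L or "N" in R or len(R) < _PARAMS.flank_len:
        return False
    return (classify_indel_sequence(S, L, R).verdict == Verdict.RANDOM
            and flank_is_random(L, R))


def _ins_ok_random(ref: np.ndarray, pos: int, S: str) -> bool:
    anchor0 = pos - 1
    a = _decode(ref, anchor0, anchor0 + 1)
    if a == "N" or S[-1] == a:
        return False
    L, R = _context(ref, pos, 1)
    if "N" in L or "N" in R or len(R) < _PARAMS.flank_len:
        return False
    return (classify_indel_sequence(S, L, R).verdict == Verdict.RANDOM
            and flank_is_random(L, R))


# ---------------------------------------------------------------------------
# haplotype sampling


def _sample_codes(rng: np.random.Generator, pop_sizes: dict,
                  freqs_by_pop: dict[str, np.ndarray]) -> np.ndarray:
    """(n_samples, 2) allele codes, samples ordered AFR..SAS blocks."""
    blocks = []
    for pop in POPULATIONS:
        n_h = 2 * pop_sizes[pop]
        p = np.asarray(freqs_by_pop[pop], dtype=float)
        p = p / p.sum()
        counts = rng.multinomial(n_h, p)
        codes = np.repeat(np.arange(len(p)), counts)
        rng.shuffle(codes)
        blocks.append(codes.reshape(-1, 2))
    return np.concatenate(blocks).astype(np.int16)


def _realized(codes: np.ndarray, pop_sizes: dict,
              n_alleles: int) -> tuple[list[float], dict[str, list[float]]]:
    total = np.bincount(codes.ravel(), minlength=n_alleles)
    glob = (total / total.sum()).tolist()
    per_pop = {}
    i = 0
    for pop in POPULATIONS:
        n = pop_sizes[pop]
        sub = codes[i:i + n]
        per_pop[pop] = (np.bincount(sub.ravel(), minlength=n_alleles)
                        / (2 * n)).tolist()
        i += n
    return glob, per_pop


def _perturb_pop_freqs(rng: np.random.Generator, f: np.ndarray,
                       kappa: float = 300.0) -> dict[str, np.ndarray]:
    """Mild Dirichlet differentiation around global targets; AFR gets a
    minor-allele boost so third-and-rarer alleles run highest there."""
    out = {}
    f = np.asarray(f, dtype=float)
    for pop in POPULATIONS:
        g = rng.dirichlet(np.maximum(f * kappa, 1e-3))
        if pop == "AFR" and len(f) > 2:
            g = g.copy()
            g[2:] *= 1.4
            g /= g.sum()
        if pop == "EAS" and len(f) > 2:
            g = g.copy()
            g[2:] *= 0.7
            g /= g.sum()
        out[pop] = g
    return out


# ---------------------------------------------------------------------------
# planting


@dataclass
class _Plant:
    """Canonical merged representation of one planted site."""
    vid: str
    vtype: str
    chrom: str
    pos: int
    ref: str
    alts: list[str]
    kinds: list[str]
    classes: list[str]          # per alt: RANDOM/…/SNP
    flank_ok: bool
    codes: np.ndarray           # (n_samples, 2)
    target_global: list[float]
    cluster_id: str | None = None


def _canonical(pos, ref, alt_atoms) -> tuple[str, list[str]]:
    """Merged REF/ALT representation given per-allele atoms (ref_i, alt_i)
    all anchored at ``pos``: longest REF wins, shorter atoms are extended."""
    full_ref = max((r for r, _ in alt_atoms), key=len)
    alts = []
    for r, a in alt_atoms:
        alts.append(a + full_ref[len(r):])
    order = sorted(range(len(alts)), key=lambda i: (len(alts[i]), alts[i]))
    return full_ref, [alts[i] for i in order], order


class SynthesisError(ValueError):
    pass


def _check_targets(freqs: np.ndarray) -> None:
    if np.any(np.asarray(freqs) < 0) or abs(np.sum(freqs) - 1.0) > 1e-9:
        raise SynthesisError(f"infeasible target frequencies {freqs}")


def plant_variants(reference: dict[str, np.ndarray], spec: ScenarioSpec,
                   rng: np.random.Generator
                   ) -> tuple[list[_Plant], list[dict]]:
    """Plant every scripted variant; returns site plants and cluster records.

    Mutates ``reference`` where expansions or flank arrays must exist in
    the genomic context.
    """
    placer = _Placer(spec, rng)
    pop_sizes = spec.pop_sizes
    plants: list[_Plant] = []
    clusters: list[dict] = []
    serial = 0

    def next_id(prefix: str) -> str:
        nonlocal serial
        serial += 1
        return f"{prefix}{serial:05d}"

    def sample(targets: np.ndarray, pops: dict | None = None) -> np.ndarray:
        _check_targets(np.asarray(targets))
        fb = pops or _perturb_pop_freqs(rng, np.asarray(targets))
        return _sample_codes(rng, pop_sizes, fb)

    def place_random_del(d: int) -> tuple[str, int]:
        for _ in range(500):
            chrom, pos = placer.place(d + 1)
            if _del_ok_random(reference[chrom], pos, d):
                return chrom, pos
        raise RuntimeError("placement failed for deletion")

    def random_ins_seq(n: int, anchor: str) -> str:
        while True:
            S = _random_seq(rng, n)
            if S[-1] != anchor:
                return S

    # ---- plain SNPs -----------------------------------------------------
    for _ in range(spec.n_snp):
        chrom, pos = placer.place(1)
        arr = reference[chrom]
        a = _decode(arr, pos - 1, pos)
        if a == "N":
            continue
        b = rng.choice([x for x in "ACGT" if x != a])
        maf = rng.uniform(0.03, 0.5)
        codes = sample(np.array([1 - maf, maf]))
        plants.append(_Plant(next_id("snp"), "snp", chrom, pos, a, [b],
                             ["SNP"], ["SNP"], True, codes, [1 - maf, maf]))

    # ---- isolated bi-allelic random indels ------------------------------
    for _ in range(spec.n_biallelic_indel):
        is_del = rng.random() < 0.5
        n = _indel_len(rng)
        maf = rng.uniform(0.03, 0.5)
        if is_del:
            chrom, pos = place_random_del(n)
            arr = reference[chrom]
            a = _decode(arr, pos - 1, pos)
            ref_a, alt_a = a + _decode(arr, pos, pos + n), a
        else:
            for _ in range(500):
                chrom, pos = placer.place(1)
                arr = reference[chrom]
                a = _decode(arr, pos - 1, pos)
                if a == "N":
                    continue
                S = random_ins_seq(n, a)
                if _ins_ok_random(arr, pos, S):
                    break
            else:
                raise RuntimeError("placement failed for insertion")
            ref_a, alt_a = a, a + S
        codes = sample(np.array([1 - maf, maf]))
        plants.append(_Plant(next_id("ind"), "biallelic_indel", chrom, pos,
                             ref_a, [alt_a], [classify_alt(ref_a, alt_a).value],
                             ["RANDOM"], True, codes, [1 - maf, maf]))

    # ---- expansion (repeat-unit) bi-allelic indels: filtered class ------
    # planted in minimal left-normalized form: the u^c array is written into
    # the reference right of the anchor and the variant deletes its first
    # copy; the anchor base is chosen so no further left shift is possible
    for _ in range(spec.n_expansion_indel):
        unit_len = int(rng.integers(1, 6))
        copies = int(rng.integers(2, 5))
        chrom, pos = placer.place(unit_len * copies + 1)
        arr = reference[chrom]
        a = _decode(arr, pos - 1, pos)
        if a == "N":
            continue
        while True:
            if unit_len == 1:
                unit = str(rng.choice([x for x in "ACGT" if x != a]))
            else:
                unit = _random_seq(rng, unit_len)
            if unit[-1] != a and len(set(unit)) >= min(unit_len, 2):
                break
        arr[pos: pos + unit_len * copies] = np.frombuffer(
            (unit * copies).encode(), dtype=np.uint8)
        ref_a, alt_a = a + unit, a
        maf = rng.uniform(0.03, 0.4)
        codes = sample(np.array([1 - maf, maf]))
        plants.append(_Plant(next_id("exp"), "expansion_indel", chrom, pos,
                             ref_a, [alt_a], ["DEL"],
                             ["MULTIMER_EXPANSION" if unit_len > 1 else
                              "MONOMERIC_EXPANSION"],
                             True, codes, [1 - maf, maf]))

    # ---- multi-allelic sites -------------------------------------------
    def plant_multiallelic(vtype: str, targets: np.ndarray,
                           n_indel_alts: int, with_snp: bool = False,
                           bad_allele: str | None = None,
                           break_flank: bool = False,
                           pops: dict | None = None) -> None:
        """Plant one multi-allelic site: ref + indel alts (+ optional SNP).

        ``bad_allele``: make one alt a repeat expansion.  ``break_flank``:
        write a tandem array into the left flank.
        Allele order in ``targets``: [ref, alt1, alt2, ...].
        """
        for _attempt in range(500):
            d_total = _indel_len(rng)  # deletion span when a DEL allele exists
            chrom, pos = placer.place(d_total + 1)
            arr = reference[chrom]
            a = _decode(arr, pos - 1, pos)
            if a == "N":
                continue
            atoms: list[tuple[str, str]] = []   # (ref_i, alt_i) at pos
            classes: list[str] = []
            ok = True
            kinds_plan = (["DEL"] + ["INS"] * (n_indel_alts - 1)
                          if rng.random() < 0.7 else ["INS"] * n_indel_alts)
            used_lens: set[int] = set()
            for kind in kinds_plan:
                if kind == "DEL":
                    if not _del_ok_random(arr, pos, d_total):
                        ok = False
                        break
                    atoms.append((a + _decode(arr, pos, pos + d_total), a))
                    classes.append("RANDOM")
                else:
                    for _ in range(50):
                        n = _indel_len(rng)
                        if n in used_lens:
                            continue
                        S = random_ins_seq(n, a)
                        if _ins_ok_random(arr, pos, S):
                            used_lens.add(n)
                            atoms.append((a, a + S))
                            classes.append("RANDOM")
                            break
                    else:
                        ok = False
                        break
            if not ok:
                continue
            if bad_allele is not None:
                if bad_allele[-1] == a:  # keep left-normalization stable
                    continue
                atoms.append((a, a + bad_allele))
                classes.append("MULTIMER_EXPANSION"
                               if len(set(bad_allele)) > 1 else
                               "MONOMERIC_EXPANSION")
            if with_snp:
                b = str(rng.choice([x for x in "ACGT" if x != a]))
                atoms.append((a, b))
                classes.append("SNP")
            flank_ok = True
            if break_flank:
                # a perfect 4x"AC" array in the left flank trips the flank
                # randomness test (8 bp array, unit 2) for every allele
                arr[pos - 12: pos - 4] = np.frombuffer(b"ACACACAC",
                                                       dtype=np.uint8)
                flank_ok = False
            full_ref, alts, order = _canonical(pos, a, atoms)
            if len(set(alts)) != len(alts):
                continue
            kinds = [classify_alt(full_ref, x) for x in alts]
            classes_ord = [classes[i] for i in order]
            targets_arr = np.asarray(targets, dtype=float)
            # reorder alt targets (and per-pop vectors) to canonical order
            tgt = [targets_arr[0]] + [float(targets_arr[1 + i]) for i in order]
            pops_ord = None
            if pops is not None:
                pops_ord = {p: np.array([v[0]] + [v[1 + i] for i in order])
                            for p, v in pops.items()}
            codes = sample(np.asarray(tgt), pops_ord)
            plants.append(_Plant(next_id("ma"), vtype, chrom, pos, full_ref,
                                 alts, [k.value for k in kinds], classes_ord,
                                 flank_ok, codes, tgt))
            return
        raise RuntimeError(f"placement failed for {vtype}")

    for _ in range(spec.n_ma_qualifying):
        k = 3 if rng.random() < 0.8 else 4
        if k == 3:
            f3 = rng.uniform(0.04, 0.15)
            f2 = rng.uniform(0.08, 0.3)
            targets = np.array([1 - f2 - f3, f2, f3])
        else:
            f4 = rng.uniform(0.04, 0.08)
            f3 = rng.uniform(0.05, 0.12)
            f2 = rng.uniform(0.08, 0.25)
            targets = np.array([1 - f2 - f3 - f4, f2, f3, f4])
        plant_multiallelic("ma_qualifying", targets, k - 1)

    for _ in range(spec.n_ma_lowfreq):
        f2 = rng.uniform(0.08, 0.3)
        targets = np.array([1 - f2 - 0.004, f2, 0.004])
        plant_multiallelic("ma_lowfreq", targets, 2)

    for _ in range(spec.n_ma_expansion_allele):
        unit = _random_seq(rng, int(rng.integers(2, 5)))
        bad = unit * int(rng.integers(2, 4))
        f3 = rng.uniform(0.04, 0.12)
        f2 = rng.uniform(0.08, 0.25)
        fbad = rng.uniform(0.05, 0.15)
        targets = np.array([1 - f2 - f3 - fbad, f2, f3, fbad])
        plant_multiallelic("ma_expansion_allele", targets, 2, bad_allele=bad)

    for _ in range(spec.n_ma_flank_repeat):
        f3 = rng.uniform(0.04, 0.12)
        f2 = rng.uniform(0.08, 0.25)
        targets = np.array([1 - f2 - f3, f2, f3])
        plant_multiallelic("ma_flank_repeat", targets, 2, break_flank=True)

    for _ in range(spec.n_ma_with_snp_alt):
        fsnp = rng.uniform(0.05, 0.2)
        f3 = rng.uniform(0.04, 0.12)
        f2 = rng.uniform(0.08, 0.25)
        targets = np.array([1 - f2 - f3 - fsnp, f2, f3, fsnp])
        plant_multiallelic("ma_with_snp_alt", targets, 2, with_snp=True)

    for _ in range(spec.n_ma_pop_specific):
        home = POPULATIONS[int(rng.integers(0, 5))]
        f2 = rng.uniform(0.1, 0.3)
        f3_home = rng.uniform(0.06, 0.12)
        targets = np.array([1 - f2 - f3_home / 5, f2, f3_home / 5])
        pops = {}
        for pop in POPULATIONS:
            f3 = f3_home if pop == home else 0.0
            pops[pop] = np.array([1 - f2 - f3, f2, f3])
        plant_multiallelic("ma_pop_specific", targets, 2, pops=pops)

    # ---- clusters -------------------------------------------------------
    def plant_cluster(vtype: str, n_members: int, gaps: list[int],
                      combos: list[tuple[int, ...]], freqs: np.ndarray,
                      ma_member: bool = False) -> None:
        """Plant adjacent indel members with joint haplotype sampling."""
        for _attempt in range(500):
            member_defs = []  # (offset_from_first_anchor, ref, alt(s))
            # decide member shapes first so span is known
            shapes = []
            for mi in range(n_members):
                is_del = rng.random() < 0.5
                n = min(_indel_len(rng), 10)
                shapes.append(("DEL" if is_del else "INS", n))
            if ma_member:
                shapes[0] = ("MA", min(_indel_len(rng), 8))
            span = sum(d for k, d in shapes if k != "INS") + n_members + sum(gaps) + 2
            chrom, pos0 = placer.place(span + 5)
            arr = reference[chrom]
            members: list[_Plant] = []
            p = pos0
            ok = True
            for mi, (kind, n) in enumerate(shapes):
                a = _decode(arr, p - 1, p)
                if a == "N":
                    ok = False
                    break
                if kind == "DEL":
                    if not _del_ok_random(arr, p, n):
                        ok = False
                        break
                    ref_a, alts_a = a + _decode(arr, p, p + n), [a]
                    classes = ["RANDOM"]
                    end = p + n
                elif kind == "INS":
                    S = random_ins_seq(n, a)
                    if not _ins_ok_random(arr, p, S):
                        ok = False
                        break
                    ref_a, alts_a = a, [a + S]
                    classes = ["RANDOM"]
                    end = p
                else:  # MA: deletion + insertion alts at one member site
                    if not _del_ok_random(arr, p, n):
                        ok = False
                        break
                    S = random_ins_seq(min(n + 2, 10), a)
                    if not _ins_ok_random(arr, p, S):
                        ok = False
                        break
                    dref = a + _decode(arr, p, p + n)
                    full_ref, alts_a, _ord = _canonical(p, a, [(dref, a),
                                                               (a, a + S)])
                    ref_a = full_ref
                    classes = ["RANDOM", "RANDOM"]
                    end = p + n
                members.append(_Plant("", "cluster_member", chrom, p, ref_a,
                                      alts_a,
                                      [classify_alt(ref_a, x).value
                                       for x in alts_a],
                                      classes, True, None, []))
                if mi < n_members - 1:
                    p = end + gaps[mi] + 1
            if not ok:
                continue
            # joint haplotype sampling over combos
            _check_targets(freqs)
            combo_codes = sample(np.asarray(freqs))
            cid = next_id("cl")
            for mi, m in enumerate(members):
                m.vid = f"{cid}m{mi}"
                m.cluster_id = cid
                mapping = np.array([c[mi] for c in combos], dtype=np.int16)
                m.codes = mapping[combo_codes]
                m.target_global = []
            plants.extend(members)
            glob, per_pop = _realized(combo_codes, pop_sizes, len(combos))
            clusters.append({
                "cluster_id": cid,
                "type": vtype,
                "chrom": chrom,
                "member_ids": [m.vid for m in members],
                "member_pos": [m.pos for m in members],
                "gaps": list(gaps),
                "combos": ["-".join(map(str, c)) for c in combos],
                "target_freqs": list(map(float, freqs)),
                "realized_global_freq": glob,
                "realized_pop_freq": per_pop,
                "combo_codes_counts": np.bincount(
                    combo_codes.ravel(), minlength=len(combos)).tolist(),
            })
            return
        raise RuntimeError(f"placement failed for cluster {vtype}")

    def three_of_four(rng) -> tuple[list[tuple[int, int]], np.ndarray]:
        f1 = rng.uniform(0.1, 0.25)
        f2 = rng.uniform(0.08, 0.2)
        return ([(0, 0), (1, 0), (0, 1)],
                np.array([1 - f1 - f2, f1, f2]))

    for _ in range(spec.n_cluster_pair):
        combos, freqs = three_of_four(rng)
        gap = int(rng.integers(1, spec.max_gap + 1))
        plant_cluster("cluster_pair", 2, [gap], combos, freqs)

    for _ in range(spec.n_cluster_triple):
        f = np.array([0.55, 0.2, 0.15, 0.1])
        combos = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        gaps = [int(rng.integers(1, spec.max_gap + 1)) for _ in range(2)]
        plant_cluster("cluster_triple", 3, gaps, combos, f)

    for _ in range(spec.n_cluster_four_combo):
        combos = [(0, 0), (1, 0), (0, 1), (1, 1)]
        freqs = np.array([0.5, 0.2, 0.18, 0.12])
        gap = int(rng.integers(1, spec.max_gap + 1))
        plant_cluster("cluster_four_combo", 2, [gap], combos, freqs)

    for _ in range(spec.n_cluster_linked):
        combos = [(0, 0), (1, 1)]
        f1 = rng.uniform(0.15, 0.4)
        gap = int(rng.integers(1, spec.max_gap + 1))
        plant_cluster("cluster_linked", 2, [gap], combos,
                      np.array([1 - f1, f1]))

    for _ in range(spec.n_cluster_wide):
        combos, freqs = three_of_four(rng)
        gap = int(rng.integers(spec.max_gap + 5, spec.max_gap + 40))
        plant_cluster("cluster_wide", 2, [gap], combos, freqs)

    for _ in range(spec.n_cluster_ma_member):
        combos = [(0, 0), (1, 0), (2, 0), (0, 1)]
        freqs = np.array([0.5, 0.2, 0.15, 0.15])
        gap = int(rng.integers(1, spec.max_gap + 1))
        plant_cluster("cluster_ma_member", 2, [gap], combos, freqs,
                      ma_member=True)

    # ---- chrX records (excluded downstream) -----------------------------
    if spec.chrx_length:
        for i in range(spec.n_chrx_records):
            pos = 1000 + i * 2000
            arr = reference["chrX"]
            a = _decode(arr, pos - 1, pos)
            if a == "N":
                continue
            b = [x for x in "ACGT" if x != a][0]
            maf = 0.2
            codes = sample(np.array([1 - maf, maf]))
            plants.append(_Plant(next_id("x"), "chrx_snp", "chrX", pos, a,
                                 [b], ["SNP"], ["SNP"], True, codes,
                                 [1 - maf, maf]))

    return plants, clusters


# ---------------------------------------------------------------------------
# genetic map / annotations


def generate_genetic_map(spec: ScenarioSpec, rng: np.random.Generator,
                         path: Path) -> list[dict]:
    """Piecewise-constant rates per autosome, HapMap-II style 4-column text.

    chr2's map deliberately stops short of the chromosome end so bins with
    no map coverage exist.
    """
    rows = []
    segs = []
    for chrom, length in spec.chrom_lengths.items():
        end = length if chrom != "chr2" else length - 500_000
        positions = list(range(1, end + 1, spec.map_segment_len))
        if positions[-1] != end:
            positions.append(end)
        cm = 0.0
        for i, p in enumerate(positions):
            rate = float(rng.lognormal(0.0, 0.8)) if i < len(positions) - 1 else 0.0
            rows.append((chrom, p, rate, cm))
            if i < len(positions) - 1:
                seg_len = positions[i + 1] - p
                segs.append({"chrom": chrom, "start": p,
                             "end": positions[i + 1] - 1, "rate": rate})
                cm += rate * seg_len / 1e6
    with open(path, "w") as fh:
        fh.write("Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)\n")
        for chrom, p, rate, cm in rows:
            fh.write(f"{chrom}\t{p}\t{rate:.6f}\t{cm:.6f}\n")
    return segs


def generate_annotations(spec: ScenarioSpec, rng: np.random.Generator,
                         bed_path: Path, gff_path: Path) -> dict:
    """Non-overlapping repeat intervals (BED) and gene models (GFF3) with
    CDS within exon within gene nesting."""
    kinds = ["SINE", "LINE", "LTR", "DNA"]
    names = {"SINE": "AluY", "LINE": "L1", "LTR": "ERVL", "DNA": "MER1"}
    repeats = []
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_lengths}

    def free(chrom, s, e):
        for (a, b) in reserved[chrom]:
            if a < e and s < b:
                return False
        return True

    chroms = list(spec.chrom_lengths)
    for _ in range(spec.n_repeats):
        for _try in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(150, 6000))
            s = int(rng.integers(0, spec.chrom_lengths[chrom] - length))
            if free(chrom, s, s + length):
                reserved[chrom].append((s, s + length))
                kind = kinds[int(rng.integers(0, len(kinds)))]
                repeats.append({"chrom": chrom, "start": s, "end": s + length,
                                "name": names[kind], "kind": kind})
                break
    genes = []
    gene_reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def gene_free(chrom, s, e):
        for (a, b) in gene_reserved[chrom]:
            if a < e and s < b:
                return False
        return True

    for gi in range(spec.n_genes):
        for _try in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(20_000, 150_000))
            s = int(rng.integers(0, spec.chrom_lengths[chrom] - length))
            if not gene_free(chrom, s, s + length):
                continue
            gene_reserved[chrom].append((s, s + length))
            n_exons = int(rng.integers(2, 6))
            bounds = np.sort(rng.choice(
                np.arange(s + 100, s + length - 100), size=2 * n_exons,
                replace=False))
            exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1]))
                     for i in range(n_exons)
                     if bounds[2 * i + 1] - bounds[2 * i] >= 50]
            if not exons:
                continue
            cds = []
            for (es, ee) in exons[:-1] if len(exons) > 1 else exons:
                if rng.random() < 0.6:
                    pad = min(20, (ee - es) // 4)
                    cds.append((es + pad, ee - pad))
            genes.append({"gene_id": f"G{gi:03d}", "chrom": chrom,
                          "start": s, "end": s + length,
                          "exons": exons, "cds": cds})
            break

    with open(bed_path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r["chrom"], r["start"])):
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['name']}\t"
                     f"{r['kind']}\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g["chrom"], g["start"])):
            gid = g["gene_id"]
            fh.write(f"{g['chrom']}\tsynth\tgene\t{g['start'] + 1}\t{g['end']}"
                     f"\t.\t+\t.\tID={gid}\n")
            for i, (es, ee) in enumerate(g["exons"]):
                fh.write(f"{g['chrom']}\tsynth\texon\t{es + 1}\t{ee}\t.\t+\t."
                         f"\tID={gid}.e{i};Parent={gid}\n")
            for i, (cs, ce) in enumerate(g["cds"]):
                fh.write(f"{g['chrom']}\tsynth\tCDS\t{cs + 1}\t{ce}\t.\t+\t0"
                         f"\tID={gid}.c{i};Parent={gid}\n")
    return {"repeats": repeats, "genes": genes}


# ---------------------------------------------------------------------------
# expected verdicts + dataset assembly


def _expected_multiallelic(entry: dict, af_min: float) -> tuple[bool, str]:
    if entry["chrom"] == "chrX":
        return False, "not_autosome"
    indel_idx = [i for i, k in enumerate(entry["kinds"])
                 if k in ("INS", "DEL")]
    if len(indel_idx) < 2:
        return False, "lt2_indel_alts"
    if not entry["flank_ok"]:
        return False, "flank_repeat"
    if any(entry["classes"][i] != "RANDOM" for i in indel_idx):
        return False, "allele_not_random"
    freqs = entry["realized_global_freq"]
    valid = int(freqs[0] > af_min) + sum(freqs[i + 1] > af_min
                                         for i in indel_idx)
    if valid < 3:
        return False, "lt3_valid_alleles"
    return True, "kept"


def _expected_multi_indels(cluster: dict, af_min: float,
                           max_gap: int) -> list[dict]:
    """Chain members at <= max_gap, then apply the haplotype-allele count
    criterion on realized combo counts marginalized to each chain."""
    gaps = cluster["gaps"]
    members = list(range(len(cluster["member_pos"])))
    chains: list[list[int]] = [[members[0]]]
    for mi, gap in zip(members[1:], gaps):
        if gap <= max_gap:
            chains[-1].append(mi)
        else:
            chains.append([mi])
    out = []
    combos = [tuple(map(int, c.split("-"))) for c in cluster["combos"]]
    counts = cluster["combo_codes_counts"]
    total = sum(counts)
    for chain in chains:
        if len(chain) < 2:
            continue
        marg: dict[tuple, int] = {}
        for combo, n in zip(combos, counts):
            key = tuple(combo[i] for i in chain)
            marg[key] = marg.get(key, 0) + n
        n_valid = sum(n / total > af_min for n in marg.values())
        if n_valid >= 3:
            out.append({
                "cluster_id": cluster["cluster_id"],
                "chrom": cluster["chrom"],
                "member_pos": [cluster["member_pos"][i] for i in chain],
                "n_haplotype_alleles": len([n for n in marg.values() if n]),
                "n_valid_alleles": int(n_valid),
            })
    return out


@dataclass
class SynthDataset:
    """Paths to the emitted files plus the in-memory truth manifest."""
    outdir: Path
    reference_fa: Path
    vcf: Path
    panel_tsv: Path
    genetic_map: Path
    repeats_bed: Path
    genes_gff: Path
    manifest_json: Path
    manifest: dict


def _make_panel(spec: ScenarioSpec) -> Panel:
    samples = []
    for pop in POPULATIONS:
        for i in range(spec.pop_sizes[pop]):
            samples.append(SampleInfo(f"{pop}{i:03d}", pop))
    return Panel(samples)


def generate_dataset(spec: ScenarioSpec, outdir: str | Path,
                     seed: int) -> SynthDataset:
    """Generate the full synthetic input set under ``outdir``.

    Identical (spec, seed) pairs produce byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    panel = _make_panel(spec)

    reference = generate_reference(spec, rng)
    plants, clusters = plant_variants(reference, spec, rng)

    # realized frequencies per plant
    variants = []
    for p in plants:
        glob, per_pop = _realized(p.codes, spec.pop_sizes,
                                  1 + len(p.alts))
        entry = {
            "id": p.vid, "type": p.vtype, "chrom": p.chrom, "pos": p.pos,
            "ref": p.ref, "alts": p.alts, "kinds": p.kinds,
            "classes": p.classes, "flank_ok": p.flank_ok,
            "cluster_id": p.cluster_id,
            "target_global_freq": list(map(float, p.target_global)),
            "realized_global_freq": glob,
            "realized_pop_freq": per_pop,
        }
        variants.append(entry)

    expected_ma = []
    for entry in variants:
        keep, reason = _expected_multiallelic(entry, spec.af_min)
        entry["expected_multiallelic"] = keep
        entry["verdict_reason"] = reason
        if keep:
            expected_ma.append({"chrom": entry["chrom"], "pos": entry["pos"],
                                "alts": entry["alts"], "id": entry["id"]})
    expected_mi = []
    for cluster in clusters:
        found = _expected_multi_indels(cluster, spec.af_min, spec.max_gap)
        cluster["expected_multi_indels"] = found
        expected_mi.extend(found)

    # emit files ----------------------------------------------------------
    ref_path = outdir / "reference.fa"
    seqs = {c: a.tobytes().decode() for c, a in reference.items()}
    write_fasta(seqs, ref_path)

    vcf_path = outdir / "cohort.vcf"
    contigs = dict(spec.chrom_lengths)
    if spec.chrx_length:
        contigs["chrX"] = spec.chrx_length
    sites = []
    for p in plants:
        sites.append(IndelSite(p.chrom, p.pos, p.ref, list(p.alts),
                               p.codes.copy()))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    emitted = []
    for s in sites:
        if len(s.alts) > 1 and rng.random() < spec.split_prob:
            for ai, alt in enumerate(s.alts, start=1):
                gt = np.where(s.genotypes == ai, 1,
                              np.where(s.genotypes < 0, -1, 0)).astype(np.int16)
                emitted.append(IndelSite(s.chrom, s.pos, s.ref, [alt], gt))
        else:
            emitted.append(s)
    write_phased_vcf(emitted, panel, vcf_path, contigs)

    panel_path = outdir / "panel.tsv"
    panel.write(panel_path)

    map_path = outdir / "genetic_map.txt"
    segs = generate_genetic_map(spec, rng, map_path)

    bed_path = outdir / "repeats.bed"
    gff_path = outdir / "genes.gff3"
    ann = generate_annotations(spec, rng, bed_path, gff_path)

    # bin-level expected counts (100 kb)
    width = 100_000
    bin_counts: dict[str, dict[str, list[int]]] = {}
    for chrom, length in spec.chrom_lengths.items():
        nb = (length + width - 1) // width
        bin_counts[chrom] = {"mm": [0] * nb, "snp": [0] * nb, "indel": [0] * nb}
    for entry in variants:
        if entry["chrom"] not in bin_counts:
            continue
        b = (entry["pos"] - 1) // width
        if all(k == "SNP" for k in entry["kinds"]):
            bin_counts[entry["chrom"]]["snp"][b] += 1
        if any(k in ("INS", "DEL") for k in entry["kinds"]):
            bin_counts[entry["chrom"]]["indel"][b] += 1
    for m in expected_ma:
        bin_counts[m["chrom"]]["mm"][(m["pos"] - 1) // width] += 1
    for m in expected_mi:
        bin_counts[m["chrom"]]["mm"][(m["member_pos"][0] - 1) // width] += 1

    manifest = {
        "seed": seed,
        "pop_sizes": dict(spec.pop_sizes),
        "chrom_lengths": dict(spec.chrom_lengths),
        "af_min": spec.af_min,
        "max_gap": spec.max_gap,
        "variants": variants,
        "clusters": clusters,
        "expected_multiallelic": expected_ma,
        "expected_multi_indels": expected_mi,
        "map_segments": segs,
        "annotations": ann,
        "bin_counts": bin_counts,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)

    return SynthDataset(outdir, ref_path, vcf_path, panel_path, map_path,
                        bed_path, gff_path, manifest_path, manifest)
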