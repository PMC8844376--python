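"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: the junction scan
enumerates every tandem array by direct string multiplication, the
normalization oracle enumerates every equivalent variant representation,
and the MDV oracle is the printed arithmetic applied literally.
"""

from __future__ import annotations


def junction_scan_expansion(S: str, L: str, R: str, max_unit: int = 15) -> bool:
    """True iff some perfect tandem array (>= 2 full adjacent copies of a
    unit of length 1..max_unit) inside L+S+R contains the whole S span."""
    T = L + S + R
    a, b = len(L), len(L) + len(S)
    n = len(T)
    for q in range(1, max_unit + 1):
        for s0 in range(0, n - 2 * q + 1):
            unit = T[s0:s0 + q]
            c = 1
            while T[s0 + c * q: s0 + (c + 1) * q] == unit:
                c += 1
            if c >= 2 and s0 <= a and s0 + c * q >= b:
                return True
    return False


def flank_has_repeat_bruteforce(flank: str, homopolymer_max: int = 5,
                                array_min_len: int = 8,
                                array_min_copies: int = 2,
                                max_unit: int = 15) -> bool:
    n = len(flank)
    for run_len in range(homopolymer_max + 1, n + 1):
        for s0 in range(0, n - run_len + 1):
            if len(set(flank[s0:s0 + run_len])) == 1:
                return True
    for q in range(2, max_unit + 1):
        for s0 in range(0, n - 2 * q + 1):
            unit = flank[s0:s0 + q]
            c = 1
            while flank[s0 + c * q: s0 + (c + 1) * q] == unit:
                c += 1
            if c >= array_min_copies and c * q >= array_min_len:
                return True
    return False


def enumerate_normalizations(seq: str, pos: int, ref: str, alt: str):
    """All VCF-valid (pos, ref, alt) representations equivalent to applying
    the given variant to ``seq`` (1-based pos).  Brute force: every
    substring replacement producing the same mutated sequence."""
    mutated = seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]
    out = []
    for p in range(1, len(seq) + 1):
        for rlen in range(0, len(seq) - p + 2):
            alen = len(mutated) - (len(seq) - rlen)
            if alen < 0:
                continue
            r = seq[p - 1: p - 1 + rlen]
            a = mutated[p - 1: p - 1 + alen]
            if not r or not a:
                continue
            if seq[:p - 1] + a + seq[p - 1 + rlen:] == mutated:
                out.append((p, r, a))
    return out


def leftmost_minimal(representations):
    """The canonical normalized form: most parsimonious (shortest total
    allele length), then leftmost position."""
    return min(representations, key=lambda t: (len(t[1]) + len(t[2]), t[0]))


def mdv_direct(counts: dict[int, int], s: int) -> float:
    N = lambda d: counts.get(d, 0)
    return (N(s - 2) + N(s - 1)) / 2 - (N(s + 1) + N(s + 2)) / 2


def span_partitions(n: int):
    """All partitions of range(n) into contiguous groups (ordered)."""
    if n == 0:
        yield []
        return
    for cut in range(1, n + 1):
        for rest in span_partitions(n - cut):
            yield [list(range(cut))] + [
                [i + cut for i in grp] for grp in rest]


def best_span_clustering(positions_ends, max_gap: int):
    """Exhaustive left-to-right maximal span clustering for <= ~8 sites.

    ``positions_ends``: list of (pos, ref_end).  Valid group: contiguous,
    first-to-last distance <= max_gap, every consecutive distance <=
    max_gap.  Among all valid contiguous partitions, the left-to-right
    maximal one lexicographically maximizes the sequence of group lengths
    (largest possible first group, then largest next, ...).  Groups of size
    one are dropped from the returned clustering.
    """
    n = len(positions_ends)

    def dist(i, j):
        return positions_ends[j][0] - positions_ends[i][1] - 1

    def group_ok(grp):
        if len(grp) < 2:
            return True
        if dist(grp[0], grp[-1]) > max_gap:
            return False
        return all(dist(a, b) <= max_gap for a, b in zip(grp, grp[1:]))

    best = None
    for part in span_partitions(n):
        if not all(group_ok(g) for g in part):
            continue
        key = tuple(len(g) for g in part)
        if best is None or key > best[0]:
            best = (key, [g for g in part if len(g) >= 2])
    return best[1] if best else []
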