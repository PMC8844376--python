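"""Random-sequence classification: period primitive, junction rule, flanks."""

import numpy as np
import pytest

from mmindel.seq_class import (
    ClassParams, Verdict, classify_indel_sequence, flank_is_random,
    smallest_period,
)
from helpers_oracles import junction_scan_expansion, flank_has_repeat_bruteforce


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSmallestPeriod:
    @pytest.mark.parametrize("seq,unit,copies", [
        ("ACACAC", "AC", 3),
        ("AAAA", "A", 4),
        ("ACGT", "ACGT", 1),
        ("ACGACGACG", "ACG", 3),
        ("A", "A", 1),
    ])
    def test_examples(self, seq, unit, copies):
        assert smallest_period(seq) == (unit, copies)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            smallest_period("")

    def test_agrees_with_divisor_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            seq = _rand_dna(rng, int(rng.integers(1, 31)))
            unit, copies = smallest_period(seq)
            assert unit * copies == seq
            # brute force: no shorter exact factorization exists
            for p in range(1, len(unit)):
                if len(seq) % p == 0:
                    assert seq != seq[:p] * (len(seq) // p)

    def test_aperiodic_units_recovered(self):
        """smallest_period(u^k) = (u, k) for aperiodic u up to 15 bp."""
        rng = np.random.default_rng(5)
        tried = 0
        while tried < 200:
            ulen = int(rng.integers(1, 16))
            u = _rand_dna(rng, ulen)
            if smallest_period(u)[1] != 1:
                continue  # u itself periodic: skip
            k = int(rng.integers(1, 11))
            assert smallest_period(u * k) == (u, k)
            tried += 1


class TestClassifyIndelSequence:
    L0 = "GATTCCGTAACG"
    R0 = "TTCAGCCATGGA"

    def test_pure_array_is_expansion_regardless_of_flank(self):
        cls = classify_indel_sequence("CACACA", self.L0, self.R0)
        assert cls.verdict == Verdict.MULTIMER_EXPANSION
        assert (cls.unit, cls.copies) == ("CA", 3)

    def test_single_copy_with_array_across_junction(self):
        # left flank ends with TTG: TTG|TTG forms a 2-copy array spanning
        # the junction, so the insertion is a slippage product
        cls = classify_indel_sequence("TTG", "ACCGATACGTTG", self.R0)
        assert cls.verdict == Verdict.MULTIMER_EXPANSION

    def test_single_copy_without_junction_array_is_random(self):
        cls = classify_indel_sequence("AGCTTGCA", self.L0, self.R0)
        assert cls.verdict == Verdict.RANDOM
        assert cls.unit == ""

    def test_straddling_copy_detected(self):
        # tail of S at the end of L and head of S at the start of R:
        # ...TG|TTG|T... contains the array TGT TGT
        cls = classify_indel_sequence("TTG", "ACCGATACGGTG", "TGCAGCCATGGA")
        assert cls.verdict == Verdict.MULTIMER_EXPANSION

    def test_monomeric_single_base_needs_neighbor(self):
        assert classify_indel_sequence(
            "A", self.L0, "ACCGT" + self.R0[:7]
        ).verdict == Verdict.MONOMERIC_EXPANSION
        assert classify_indel_sequence(
            "A", self.L0, self.R0).verdict == Verdict.RANDOM

    def test_monomeric_run_unconditional(self):
        cls = classify_indel_sequence("AAAA", self.L0, self.R0)
        assert cls.verdict == Verdict.MONOMERIC_EXPANSION
        assert (cls.unit, cls.copies) == ("A", 4)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_indel_sequence("ANA", self.L0, self.R0)
        with pytest.raises(ValueError):
            classify_indel_sequence("", self.L0, self.R0)

    def test_long_unit_not_an_expansion(self):
        # 16-mer repeated twice: unit exceeds the 15-bp ceiling
        u = "ACGTACGGTTCAGCAT"
        assert len(u) == 16 and smallest_period(u)[1] == 1
        cls = classify_indel_sequence(u * 2, self.L0, self.R0,
                                      ClassParams())
        assert cls.verdict == Verdict.RANDOM

    def test_agrees_with_junction_scan_oracle(self):
        """Classifier == brute-force tandem-array scan on random triples."""
        rng = np.random.default_rng(42)
        mismatches = 0
        for i in range(3000):
            if i % 3 == 0:  # bias toward repetitive structures
                ulen = int(rng.integers(1, 16))
                u = _rand_dna(rng, ulen)
                k = int(rng.integers(1, 4))
                S = u * k
            else:
                S = _rand_dna(rng, int(rng.integers(1, 25)))
            L = _rand_dna(rng, 12)
            R = _rand_dna(rng, 12)
            if rng.random() < 0.3:  # force junction situations
                cut = int(rng.integers(0, len(S) + 1))
                L = L[:12 - cut] + S[len(S) - cut:] if cut else L
                R = S[:int(rng.integers(0, len(S) + 1))] + R
                R = R[:12]
            got = classify_indel_sequence(S, L, R).verdict != Verdict.RANDOM
            want = junction_scan_expansion(S, L, R)
            mismatches += got != want
        assert mismatches == 0

    def test_reverse_complement_invariance(self):
        comp = str.maketrans("ACGT", "TGCA")

        def rc(s):
            return s.translate(comp)[::-1]

        rng = np.random.default_rng(9)
        for _ in range(500):
            S = _rand_dna(rng, int(rng.integers(1, 20)))
            if rng.random() < 0.4:
                u = _rand_dna(rng, int(rng.integers(1, 5)))
                S = u * int(rng.integers(1, 4))
            L, R = _rand_dna(rng, 12), _rand_dna(rng, 12)
            fwd = classify_indel_sequence(S, L, R).verdict
            rev = classify_indel_sequence(rc(S), rc(R), rc(L)).verdict
            assert (fwd == Verdict.RANDOM) == (rev == Verdict.RANDOM)


class TestFlankIsRandom:
    R_OK = "TTCAGCCATGGA"

    def test_homopolymer_run_fails(self):
        assert not flank_is_random("GGGGGGATCGAT", self.R_OK)

    def test_tandem_array_fails(self):
        assert not flank_is_random("ACGTACGTACGT", self.R_OK)  # 3x ACGT

    def test_random_flanks_pass(self):
        assert flank_is_random("GATTCCGTAACG", self.R_OK)

    def test_short_array_below_length_floor_passes(self):
        # 2x"AC" = 4 bp < 8 bp floor
        assert flank_is_random("ACACGTTAGCGT", self.R_OK)

    def test_either_side_can_fail(self):
        assert not flank_is_random(self.R_OK, "GGGGGGATCGAT")

    def test_agrees_with_bruteforce_scan(self):
        rng = np.random.default_rng(13)
        ok = "GATTCCGTAACG"
        for _ in range(2000):
            f = _rand_dna(rng, 12)
            if rng.random() < 0.3:
                u = _rand_dna(rng, int(rng.integers(1, 5)))
                ins = u * int(rng.integers(2, 7))
                at = int(rng.integers(0, 13))
                f = (f[:at] + ins + f[at:])[:12]
            assert flank_is_random(f, ok) == (not flank_has_repeat_bruteforce(f))
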