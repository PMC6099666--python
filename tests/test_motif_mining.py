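"""Entropy/IG/RDI arithmetic and motif mining against brute-force oracles."""

import math
import random
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imsp.motif_mining import (MotifError, compute_rdi, conditional_entropy,
                               enumerate_candidates, information_gain,
                               matches, mine_top_motifs, set_entropy,
                               validate_pattern)
from imsp.sequences import Dataset, ProteinRecord
from imsp.synthetic_data import SyntheticConfig, generate

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Brute-force oracle, independent of the implementation under test
# ---------------------------------------------------------------------------

def oracle_contains(pattern, seq):
    rx = "".join("[%s]" % AA if c == "-" else c for c in pattern)
    return re.search(rx, seq) is not None


def oracle_ig(p, n):
    def term(q):
        return q * math.log2(q * n) if q > 0 else 0.0
    return math.log2(n) - term(p) - term(1 - p)


def oracle_rdi(pattern, pos_seqs, neg_seqs):
    cp = sum(oracle_contains(pattern, s) for s in pos_seqs)
    cn = sum(oracle_contains(pattern, s) for s in neg_seqs)
    igp = oracle_ig(cp / len(pos_seqs), len(pos_seqs))
    ign = oracle_ig(cn / len(neg_seqs), len(neg_seqs))
    return (igp / math.log2(len(pos_seqs))
            - ign / math.log2(len(neg_seqs)), cp, cn)


def oracle_candidates(pos_seqs, min_support):
    """Exhaustive enumeration over all windows of all positive sequences."""
    pats = set()
    for s in pos_seqs:
        for i in range(len(s)):
            for ln in range(3, 7):
                w = s[i:i + ln]
                if len(w) < ln or any(c not in AA for c in w):
                    continue
                if 3 <= ln <= 5:
                    pats.add(w)
                for j in range(1, ln - 1):
                    if 3 <= ln - 1 <= 5:
                        pats.add(w[:j] + "-" + w[j + 1:])
    out = []
    for p in pats:
        support = sum(oracle_contains(p, s) for s in pos_seqs)
        if support >= min_support * len(pos_seqs):
            out.append(p)
    return sorted(out)


def oracle_top_k(pos_seqs, neg_seqs, k, min_support):
    scored = []
    for p in oracle_candidates(pos_seqs, min_support):
        rdi, cp, cn = oracle_rdi(p, pos_seqs, neg_seqs)
        scored.append((p, rdi, cp, cn))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return scored[:k]


# ---------------------------------------------------------------------------
# Arithmetic
# ---------------------------------------------------------------------------

class TestEntropyArithmetic:
    @pytest.mark.parametrize("n,expected", [(1, 0.0), (2, 1.0), (8, 3.0)])
    def test_set_entropy(self, n, expected):
        assert set_entropy(n) == pytest.approx(expected)

    def test_set_entropy_domain(self):
        with pytest.raises(MotifError):
            set_entropy(0)

    @pytest.mark.parametrize("p,n,expected", [
        (1.0, 8, 3.0),       # ubiquitous motif: no entropy reduction
        (0.5, 8, 2.0),       # symmetric split: one bit gained
        (0.0, 5, math.log2(5)),  # absent motif: uninformative
    ])
    def test_conditional_entropy(self, p, n, expected):
        assert conditional_entropy(p, n) == pytest.approx(expected)

    @pytest.mark.parametrize("p,n,expected", [
        (0.5, 8, 1.0),
        (0.5, 1000, 1.0),
        (1.0, 8, 0.0),
        (0.25, 16, 0.8112781244591328),  # frozen from the arithmetic oracle
    ])
    def test_information_gain(self, p, n, expected):
        assert information_gain(p, n) == pytest.approx(expected)
        assert information_gain(p, n) == pytest.approx(oracle_ig(p, n))

    @given(p=st.floats(0, 1), n=st.integers(2, 10000))
    @settings(max_examples=200, derandomize=True)
    def test_ig_nonnegative_and_symmetric(self, p, n):
        ig = information_gain(p, n)
        assert ig >= 0.0
        assert ig == pytest.approx(information_gain(1 - p, n), abs=1e-9)
        assert ig <= 1.0 + 1e-12  # maximum one bit, at p = 0.5


class TestRDI:
    def _sets(self, pos, neg):
        return (Dataset([ProteinRecord(f"p{i}", s) for i, s in enumerate(pos)]),
                Dataset([ProteinRecord(f"n{i}", s) for i, s in enumerate(neg)]))

    def test_symmetric_occurrence_is_zero(self):
        pos, neg = self._sets(["KGDAA", "WWWWW"] * 4, ["AKGDA", "YYYYY"] * 4)
        assert compute_rdi("KGD", pos, neg).rdi == pytest.approx(0.0)

    def test_absent_motif_is_zero(self):
        pos, neg = self._sets(["AAAA"] * 4, ["WWWW"] * 4)
        assert compute_rdi("KGD", pos, neg).rdi == pytest.approx(0.0)

    def test_half_of_positives_only(self):
        # 16 vs 16, motif in 8 positives and no negatives: 1/log2(16) = 0.25
        pos, neg = self._sets(["AKGDA"] * 8 + ["WWWWW"] * 8, ["YYYYY"] * 16)
        m = compute_rdi("KGD", pos, neg)
        assert m.rdi == pytest.approx(0.25)
        assert (m.count_pos, m.count_neg) == (8, 0)

    def test_singleton_class_rejected(self):
        pos, neg = self._sets(["AKGDA"], ["YYYYY"] * 4)
        with pytest.raises(MotifError):
            compute_rdi("KGD", pos, neg)

    @pytest.mark.parametrize("base", [2.0, math.e, 10.0])
    def test_rdi_base_invariant(self, base):
        pos, neg = self._sets(["AKGDAW", "KGDWWA", "WAWAWA", "YKYKYK"],
                              ["AKGDAY", "YYYYYY", "WYWYWY", "AAAAAA"])
        ref = compute_rdi("KGD", pos, neg, base=2.0).rdi
        assert compute_rdi("KGD", pos, neg, base=base).rdi == pytest.approx(ref)

    def test_ambiguity_codes_never_match(self):
        assert not matches("KGD", "AKXDA")
        assert not matches("K-D", "AKXDA".replace("X", "X"))
        assert matches("K-D", "AKWDA")


class TestPatternValidation:
    @pytest.mark.parametrize("pat", ["KGD", "LLLL", "LL-LLL", "LAL-L", "C-CR"])
    def test_valid_shapes(self, pat):
        validate_pattern(pat)

    @pytest.mark.parametrize("pat", ["KG", "-KGD", "KGD-", "K--GD",
                                     "KGDKGDK", "LLLLLL", "K1D"])
    def test_invalid_shapes(self, pat):
        with pytest.raises(MotifError):
            validate_pattern(pat)


# ---------------------------------------------------------------------------
# Enumeration and mining
# ---------------------------------------------------------------------------

class TestEnumeration:
    def test_single_string_exhaustive(self):
        ds = Dataset([ProteinRecord("a", "LLLL")])
        cands = set(enumerate_candidates(ds, min_support=1.0))
        assert cands == {"LLL", "LLLL", "LL-L", "L-LL"}
        assert cands == set(oracle_candidates(["LLLL"], 1.0))

    def test_full_support_requires_common_patterns(self):
        ds = Dataset([ProteinRecord("a", "MKLVW"),
                      ProteinRecord("b", "ACDEF")])
        assert enumerate_candidates(ds, min_support=1.0) == []

    def test_too_short_sequences_yield_nothing(self):
        ds = Dataset([ProteinRecord("a", "ML"), ProteinRecord("b", "AC")])
        assert enumerate_candidates(ds, min_support=0.5) == []


def _random_dataset(rng, n, max_len):
    return [("".join(rng.choice(AA) for _ in range(rng.randint(5, max_len))))
            for _ in range(n)]


class TestMining:
    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_oracle_on_small_sets(self, seed):
        # datasets of <= 20 sequences x length <= 30, plus shared motifs so
        # candidates actually pass the support filter
        rng = random.Random(seed)
        pos = _random_dataset(rng, rng.randint(4, 20), 30)
        neg = _random_dataset(rng, rng.randint(4, 20), 30)
        pos = [s[:3] + "KGD" + s[3:] if i % 2 else s
               for i, s in enumerate(pos)]
        got = mine_top_motifs(
            Dataset([ProteinRecord(f"p{i}", s) for i, s in enumerate(pos)]),
            Dataset([ProteinRecord(f"n{i}", s) for i, s in enumerate(neg)]),
            k=10, min_support=0.3)
        expected = oracle_top_k(pos, neg, 10, 0.3)
        assert [(m.pattern, m.count_pos, m.count_neg) for m in got] == \
            [(p, cp, cn) for p, _, cp, cn in expected]
        for m, (_, rdi, _, _) in zip(got, expected):
            assert m.rdi == pytest.approx(rdi)

    def test_identical_classes_tie_broken_deterministically(self):
        seqs = ["AKGDAW", "KGDWWA", "WAWKGD", "YKGDYK"]
        pos = Dataset([ProteinRecord(f"p{i}", s) for i, s in enumerate(seqs)])
        neg = Dataset([ProteinRecord(f"n{i}", s) for i, s in enumerate(seqs)])
        out = mine_top_motifs(pos, neg, k=5, min_support=0.5)
        assert all(m.rdi == pytest.approx(0.0) for m in out)
        # deterministic tie-break: count_pos desc, then lexicographic
        keys = [(-m.count_pos, m.pattern) for m in out]
        assert keys == sorted(keys)

    def test_k_larger_than_candidates_returns_all(self):
        pos = Dataset([ProteinRecord(f"p{i}", "AKGDA") for i in range(4)])
        neg = Dataset([ProteinRecord(f"n{i}", "WWWWW") for i in range(4)])
        out = mine_top_motifs(pos, neg, k=500, min_support=1.0)
        assert 0 < len(out) < 500

    def test_planted_motif_recovered(self):
        ds = generate(SyntheticConfig(
            n_pos=200, n_neg=200, length_range=(60, 100),
            planted_motifs=[("KGD", 0.6, 0.05)], seed=11))
        top = mine_top_motifs(ds.positives(), ds.negatives(), k=5)
        assert "KGD" in [m.pattern for m in top]
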