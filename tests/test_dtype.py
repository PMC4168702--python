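import itertools

import numpy as np
import pytest

from under2.dtype import (
    centered_counts,
    d2,
    d2s,
    d2star,
    dtype_dissimilarity,
    kmer_counts,
    null_word_probs,
)
from under2.markov import fit_markov, model_from_base_probs, uniform_model
from under2.readset import ReadSet

from conftest import random_readset


def direct_counts(reads, k):
    """Dictionary oracle for pooled k-mer counts."""
    out = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            out[w] = out.get(w, 0) + 1
    return out


class TestKmerCounts:
    def test_simple_enumeration(self):
        v = kmer_counts(ReadSet("s", ["ACGT"]), 2)
        assert (v["AC"], v["CG"], v["GT"]) == (1, 1, 1)
        assert v.positions == 3

    def test_revcomp_merge_on_palindrome(self):
        v = kmer_counts(ReadSet("s", ["ACGT"]), 4, merge_revcomp=True)
        assert v["ACGT"] == 1  # self reverse-complement: counted once

    def test_overlapping_homopolymer(self):
        v = kmer_counts(ReadSet("s", ["AAAA"]), 2)
        assert v["AA"] == 3

    def test_counts_never_span_read_boundaries(self):
        v = kmer_counts(ReadSet("s", ["AC", "GT"]), 2)
        assert v["CG"] == 0 and v.positions == 2

    def test_matches_dictionary_oracle(self, rng):
        rs = random_readset(rng, "s", n_reads=(3, 6), length=(10, 30))
        for k in (1, 2, 3, 5):
            v = kmer_counts(rs, k)
            expect = direct_counts(rs.reads, k)
            for w in expect:
                assert v[w] == expect[w]
            assert int(v.counts.sum()) == sum(expect.values())

    def test_merge_pools_reverse_complements(self, rng):
        rs = random_readset(rng, "s")
        plain = kmer_counts(rs, 3)
        merged = kmer_counts(rs, 3, merge_revcomp=True)
        assert int(plain.counts.sum()) == int(merged.counts.sum())
        assert merged["ACG"] == plain["ACG"] + plain["CGT"]

    def test_k_too_large_is_error(self):
        with pytest.raises(ValueError):
            kmer_counts(ReadSet("s", ["ACG"]), 4)


class TestRawStatistics:
    def test_d2_inner_product(self):
        a = kmer_counts(ReadSet("a", ["ACGT"]), 2)
        assert d2(a, a) == 3.0

    def test_d2_disjoint_words(self):
        a = kmer_counts(ReadSet("a", ["AAAA"]), 2)
        b = kmer_counts(ReadSet("b", ["CCCC"]), 2)
        assert d2(a, b) == 0.0

    def test_d2_self_is_sum_of_squares(self, rng):
        rs = random_readset(rng, "s")
        a = kmer_counts(rs, 2)
        assert d2(a, a) == pytest.approx(float((a.counts**2).sum()))

    def test_mismatched_k_is_error(self):
        a = kmer_counts(ReadSet("a", ["ACGT"]), 2)
        b = kmer_counts(ReadSet("b", ["ACGT"]), 3)
        with pytest.raises(ValueError):
            d2(a, b)

    def test_cauchy_schwarz_bound(self, rng):
        for _ in range(20):
            a = kmer_counts(random_readset(rng, "a"), 3)
            b = kmer_counts(random_readset(rng, "b"), 3)
            assert d2(a, b) ** 2 <= d2(a, a) * d2(b, b) + 1e-9

    def test_d2star_zero_when_counts_at_expectation(self):
        # a single read "ACGT" with k=1 under its own order-0 fit with
        # pseudocount 0: counts exactly equal positions * p_w
        rs = ReadSet("s", ["ACGT"])
        a = kmer_counts(rs, 1)
        null = fit_markov(rs, order=0, pseudocount=0)
        assert d2star(a, a, null, null) == pytest.approx(0.0, abs=1e-12)

    def test_d2s_closed_form_single_word(self):
        # one word with centred counts c on both sides: c^2 / (c sqrt 2)
        rs = ReadSet("s", ["AAAA"])
        a = kmer_counts(rs, 4)
        null = model_from_base_probs([0.7, 0.1, 0.1, 0.1])
        c = a.counts[0] - a.positions * 0.7**4
        others = -a.positions * null_word_probs(null, 4)[1:]  # all words but AAAA
        expect = c / np.sqrt(2) + np.sum(others**2 / np.sqrt(2 * others**2))
        assert d2s(a, a, null, null) == pytest.approx(float(expect))

    def test_d2star_and_d2s_match_direct_evaluation(self):
        """Printed-formula oracle on a fixed toy pair."""
        ra, rb = ReadSet("a", ["ACGT"]), ReadSet("b", ["ACGG"])
        k = 2
        a, b = kmer_counts(ra, k), kmer_counts(rb, k)
        null = uniform_model()
        p = 1 / 16
        pos = 3
        words = ["".join(w) for w in itertools.product("ACGT", repeat=2)]
        ca = {w: a[w] - pos * p for w in words}
        cb = {w: b[w] - pos * p for w in words}
        exp_star = sum(
            ca[w] * cb[w] / np.sqrt(pos * p * pos * p) for w in words
        )
        exp_s = sum(
            ca[w] * cb[w] / np.sqrt(ca[w] ** 2 + cb[w] ** 2)
            for w in words
            if ca[w] or cb[w]
        )
        assert d2star(a, b, null, null) == pytest.approx(float(exp_star))
        assert d2s(a, b, null, null) == pytest.approx(float(exp_s))

    def test_centered_counts_sum_to_zero_under_own_fit(self, rng):
        rs = random_readset(rng, "s", n_reads=(3, 6), length=(20, 30))
        a = kmer_counts(rs, 2)
        null = fit_markov(rs, order=0, pseudocount=0)
        cc = centered_counts(a, null)
        # exact only when every read has the same length (positions known);
        # uniform-length sets satisfy it to rounding
        rs2 = ReadSet("u", ["ACGTACGTAA", "CCGGTTAAGG"])
        cc2 = centered_counts(kmer_counts(rs2, 1), fit_markov(rs2, 0, 0))
        assert float(cc2.centered.sum()) == pytest.approx(0.0, abs=1e-6)


class TestDissimilarity:
    def test_self_comparison_is_zero(self, rng):
        rs = random_readset(rng, "s", n_reads=(3, 6), length=(20, 30))
        for stat in ("d2", "d2s", "d2star"):
            assert dtype_dissimilarity(rs, rs, stat) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_words_maximal_distance(self):
        r1 = ReadSet("a", ["AAAA"])
        r2 = ReadSet("b", ["CCCC"])
        assert dtype_dissimilarity(r1, r2, "d2", k=2, merge_revcomp=False) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(10):
            r1 = random_readset(rng, "a", n_reads=(2, 5), length=(15, 30))
            r2 = random_readset(rng, "b", n_reads=(2, 5), length=(15, 30))
            for stat in ("d2", "d2s", "d2star"):
                d12 = dtype_dissimilarity(r1, r2, stat, k=3)
                d21 = dtype_dissimilarity(r2, r1, stat, k=3)
                assert d12 == pytest.approx(d21, rel=1e-12)
                assert 0.0 <= d12 <= 1.0
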