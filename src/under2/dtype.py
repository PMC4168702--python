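"""Fixed-length word-count comparators: D2, D2*, D2S and their read-set forms.

The D2 statistic is the inner product of the k-mer count vectors of two
inputs; D2* and D2S standardize each count by its expectation under an
i.i.d. null before taking the product.  For read sets, counts are pooled
over reads (never spanning read boundaries) and, by default, a word and its
reverse complement are merged into one canonical entry to account for the
double strand.  Each raw similarity S is reported as a bounded
dissimilarity d = 0.5 * (1 - S / norm) in [0, 1], where norm is the
Cauchy-Schwarz bound of S, so that self-comparison gives 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import MarkovModel, fit_markov
from .readset import ReadSet

__all__ = [
    "KmerCountVector",
    "CenteredCounts",
    "kmer_counts",
    "null_word_probs",
    "centered_counts",
    "d2",
    "d2star",
    "d2s",
    "dtype_dissimilarity",
    "DTYPE_STATS",
]

DTYPE_STATS = ("d2", "d2s", "d2star")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(read: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int64)
    for ch, c in _CODE.items():
        lut[ord(ch)] = c
    return lut[np.frombuffer(read.encode("ascii"), dtype=np.uint8)]


def _revcomp_perm(k: int) -> np.ndarray:
    """Index permutation mapping each k-mer code to its reverse complement."""
    idx = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(idx)
    x = idx.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - x % 4)
        x //= 4
    return rc


def _word_index(word: str) -> int:
    i = 0
    for ch in word.upper():
        i = i * 4 + _CODE[ch]
    return i


@dataclass
class KmerCountVector:
    """Pooled k-mer occurrence counts of one read set.

    ``counts`` is indexed by the base-4 encoding of the word.  When
    ``merged`` is set, each count sits on the lexicographically smaller of
    {w, revcomp(w)} and the other entry is zero.  ``positions`` is the
    pooled number of matchable window starts, sum over reads of
    (len - k + 1), excluding windows that contain an N.
    """

    k: int
    counts: np.ndarray
    positions: int
    merged: bool = False
    label: str = ""

    def __getitem__(self, word: str) -> int:
        i = _word_index(word)
        if self.merged:
            rc = int(_revcomp_perm(self.k)[i])
            i = min(i, rc)
        return int(self.counts[i])


def kmer_counts(rs: ReadSet, k: int, merge_revcomp: bool = False) -> KmerCountVector:
    """Count k-mer occurrences pooled over the reads of a set."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 12:
        raise ValueError("word lengths above 12 are not supported")
    if k > min(len(r) for r in rs.reads):
        raise ValueError(f"k={k} exceeds the shortest read of set {rs.label!r}")
    counts = np.zeros(4**k, dtype=np.int64)
    positions = 0
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for read in rs.reads:
        codes = _encode(read)
        if len(codes) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows >= 0).all(axis=1)
        ids = windows @ weights
        counts += np.bincount(ids[valid], minlength=4**k)
        positions += int(valid.sum())
    if merge_revcomp:
        rc = _revcomp_perm(k)
        merged = counts + counts[rc]
        merged[np.arange(4**k) > rc] = 0
        pal = np.arange(4**k) == rc
        merged[pal] = counts[pal]
        counts = merged
    return KmerCountVector(k, counts, positions, merge_revcomp, rs.label)


def null_word_probs(model: MarkovModel, k: int, merge_revcomp: bool = False) -> np.ndarray:
    """p_w for all 4^k words under the model, merged like the counts."""
    logpi, logt = model.log_tables()
    p = np.exp(logpi)
    trans = np.exp(logt)
    for _ in range(k - 1):
        last = np.arange(len(p)) % 4
        p = (p[:, None] * trans[last]).ravel()
    if merge_revcomp:
        rc = _revcomp_perm(k)
        merged = p + p[rc]
        merged[np.arange(4**k) > rc] = 0
        pal = np.arange(4**k) == rc
        merged[pal] = p[pal]
        p = merged
    return p


@dataclass
class CenteredCounts:
    """Counts centred by their null expectation: A~_w = A_w - positions * p_w."""

    k: int
    centered: np.ndarray
    null_probs: np.ndarray
    positions: int


def centered_counts(a: KmerCountVector, null: MarkovModel) -> CenteredCounts:
    p = null_word_probs(null, a.k, a.merged)
    return CenteredCounts(a.k, a.counts - a.positions * p, p, a.positions)


def _check_compatible(a: KmerCountVector, b: KmerCountVector) -> None:
    if a.k != b.k:
        raise ValueError(f"mismatched word lengths: {a.k} vs {b.k}")
    if a.merged != b.merged:
        raise ValueError("cannot mix merged and unmerged count vectors")


def d2(a: KmerCountVector, b: KmerCountVector) -> float:
    """Inner product of the two k-mer count vectors."""
    _check_compatible(a, b)
    return float(np.dot(a.counts, b.counts))


def d2star(
    a: KmerCountVector, b: KmerCountVector,
    null_a: MarkovModel, null_b: MarkovModel,
) -> float:
    """D2* = sum A~_w B~_w / sqrt(pos_a p^a_w * pos_b p^b_w).

    With a single null and equal position counts this reduces to the
    textbook sum A~ B~ / ((n - k + 1) p_w); the geometric-mean form keeps
    the statistic symmetric when the two sets differ.
    """
    _check_compatible(a, b)
    ca = centered_counts(a, null_a)
    cb = centered_counts(b, null_b)
    denom = np.sqrt(a.positions * ca.null_probs * b.positions * cb.null_probs)
    mask = denom > 0
    return float(np.sum(ca.centered[mask] * cb.centered[mask] / denom[mask]))


def d2s(
    a: KmerCountVector, b: KmerCountVector,
    null_a: MarkovModel, null_b: MarkovModel,
) -> float:
    """D2S = sum A~_w B~_w / sqrt(A~_w^2 + B~_w^2); all-zero terms contribute 0."""
    _check_compatible(a, b)
    ca = centered_counts(a, null_a).centered
    cb = centered_counts(b, null_b).centered
    denom = np.sqrt(ca**2 + cb**2)
    mask = denom > 0
    return float(np.sum(ca[mask] * cb[mask] / denom[mask]))


def dtype_dissimilarity(
    r1: ReadSet,
    r2: ReadSet,
    stat: str = "d2",
    k: int = 5,
    merge_revcomp: bool = True,
    order: int = 0,
    pseudocount: float = 1.0,
) -> float:
    """Bounded dissimilarity d = 0.5 (1 - S / norm) for a d-type statistic.

    Nulls for the centred statistics are fitted on each set separately
    (order 0 by default).  The normalizer is the Cauchy-Schwarz bound of
    the respective raw statistic, so d is in [0, 1] and 0 at
    self-comparison.
    """
    if stat not in DTYPE_STATS:
        raise ValueError(f"unknown statistic {stat!r}; choose from {DTYPE_STATS}")
    a = kmer_counts(r1, k, merge_revcomp)
    b = kmer_counts(r2, k, merge_revcomp)
    if a.counts.sum() == 0 or b.counts.sum() == 0:
        raise ValueError("degenerate all-zero k-mer count vector")
    if stat == "d2":
        s = d2(a, b)
        norm = np.sqrt(d2(a, a) * d2(b, b))
    else:
        na = fit_markov(r1, order, pseudocount)
        nb = fit_markov(r2, order, pseudocount)
        ca = centered_counts(a, na).centered
        cb = centered_counts(b, nb).centered
        if stat == "d2star":
            pa = null_word_probs(na, k, merge_revcomp)
            pb = null_word_probs(nb, k, merge_revcomp)
            da = a.positions * pa
            db = b.positions * pb
            mask = (da > 0) & (db > 0)
            s = float(np.sum(ca[mask] * cb[mask] / np.sqrt(da[mask] * db[mask])))
            norm = np.sqrt(
                np.sum(ca[mask] ** 2 / da[mask]) * np.sum(cb[mask] ** 2 / db[mask])
            )
        else:  # d2s
            denom = np.sqrt(ca**2 + cb**2)
            mask = denom > 0
            s = float(np.sum(ca[mask] * cb[mask] / denom[mask]))
            norm = np.sqrt(
                np.sum(ca[mask] ** 2 / denom[mask]) * np.sum(cb[mask] ** 2 / denom[mask])
            )
    if norm == 0:
        raise ValueError("degenerate count vectors: zero normalizer")
    return float(0.5 * (1.0 - s / norm))
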