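"""Irredundant common patterns of two read sets.

A word is *shared* when it occurs at least once in each read set (directly
or, when transforms are enabled, in a reverse / complement / reverse
complement of a read).  A shared word is *irredundant* when at least one of
its occurrences is not completely contained, on the same read and
transform, inside an occurrence of a longer shared word; the irredundant
set is what the priority/untied selection downstream consumes, and its size
is bounded by |R1| + |R2|.

Two routes are provided: an exhaustive enumeration for tiny inputs
(:func:`common_patterns_bruteforce`) and the suffix-array route
(:func:`irredundant_common_patterns`) used for everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _suffix
from .readset import TRANSFORMS, Occurrence, ReadSet, _transform

__all__ = [
    "DocInfo",
    "PairIndex",
    "IrredundantSet",
    "common_patterns_bruteforce",
    "irredundant_common_patterns",
]

_BRUTE_FORCE_LIMIT = 2000

_LUT = np.full(256, -1, dtype=np.int64)
for _i, _ch in enumerate("ACGT"):
    _LUT[ord(_ch)] = _i


@dataclass(frozen=True)
class DocInfo:
    """One indexed document: a transform of one read of one set."""

    set_id: int  # 1 or 2
    read_index: int
    transform: str
    start: int  # global start position in the concatenated text
    length: int


class PairIndex:
    """Generalized suffix index over all documents of a read-set pair.

    Documents are laid out transform-block first (F, R, C, RC), within each
    block first-set reads before second-set reads; this concatenation order
    is also the coordinate system of the pattern priority rule.  Each
    document is followed by a unique sentinel code, and every N position
    receives its own sentinel so that it matches nothing.
    """

    def __init__(self, r1: ReadSet, r2: ReadSet, transforms=TRANSFORMS):
        transforms = tuple(transforms)
        if not transforms or any(t not in TRANSFORMS for t in transforms):
            raise ValueError(f"transforms must be a non-empty subset of {TRANSFORMS}")
        self.r1 = r1
        self.r2 = r2
        self.transforms = tuple(t for t in TRANSFORMS if t in transforms)

        docs: list[DocInfo] = []
        chunks: list[str] = []
        pos = 0
        for t in self.transforms:
            for set_id, rs in ((1, r1), (2, r2)):
                for idx, read in enumerate(rs.reads):
                    s = _transform(read, t)
                    docs.append(DocInfo(set_id, idx, t, pos, len(s)))
                    chunks.append(s)
                    chunks.append("\0")  # placeholder, replaced by a unique code
                    pos += len(s) + 1
        self.docs = docs
        text = np.frombuffer("".join(chunks).encode("ascii"), dtype=np.uint8)
        codes = _LUT[text].copy()
        holes = codes < 0  # sentinels between documents and N positions
        codes[holes] = 4 + np.arange(int(holes.sum()), dtype=np.int64)
        self.text = codes
        self.L = len(codes)

        self.setflag = np.full(self.L, -1, dtype=np.int64)
        self.docid = np.full(self.L, -1, dtype=np.int64)
        for d, doc in enumerate(docs):
            self.setflag[doc.start : doc.start + doc.length] = doc.set_id - 1
            self.docid[doc.start : doc.start + doc.length] = d
        self.setflag[holes] = -1  # N positions belong to no set

        self.sa = _suffix.suffix_array(self.text)
        self.rank = np.empty_like(self.sa)
        self.rank[self.sa] = np.arange(self.L, dtype=np.int64)
        self.lcp = _suffix.lcp_array(self.text, self.sa)
        # prefix counts of first/second-set positions in suffix-array order
        flags_by_rank = self.setflag[self.sa]
        self._csum1 = np.concatenate(([0], np.cumsum(flags_by_rank == 0)))
        self._csum2 = np.concatenate(([0], np.cumsum(flags_by_rank == 1)))
        self._key_cache: dict[int, np.ndarray] = {}

    def occurrence_at(self, pos: int, length: int) -> Occurrence:
        doc = self.docs[int(self.docid[pos])]
        return Occurrence(doc.set_id, doc.read_index, doc.transform, int(pos) - doc.start, int(length))

    def word_at(self, pos: int, length: int) -> str:
        return "".join("ACGT"[c] for c in self.text[pos : pos + length])

    def set_counts(self, lo: int, hi: int) -> tuple[int, int]:
        """Occurrences of the word with SA interval [lo, hi) in each set."""
        return (
            int(self._csum1[hi] - self._csum1[lo]),
            int(self._csum2[hi] - self._csum2[lo]),
        )

    def priority_key(self, orientation: int = 1) -> np.ndarray:
        """Per-position coordinate used for 'first occurrence' ordering.

        Orientation 1 is the native layout (first set before second within
        each transform block); orientation 2 swaps the two sets.
        """
        if orientation not in (1, 2):
            raise ValueError("orientation must be 1 or 2")
        if orientation in self._key_cache:
            return self._key_cache[orientation]
        if orientation == 1:
            key = np.arange(self.L, dtype=np.int64)
        else:
            order = sorted(
                range(len(self.docs)),
                key=lambda d: (
                    TRANSFORMS.index(self.docs[d].transform),
                    -self.docs[d].set_id,
                    self.docs[d].read_index,
                ),
            )
            new_start = np.empty(len(self.docs), dtype=np.int64)
            pos = 0
            for d in order:
                new_start[d] = pos
                pos += self.docs[d].length + 1
            delta = np.zeros(len(self.docs) + 1, dtype=np.int64)
            for d, doc in enumerate(self.docs):
                delta[d] = new_start[d] - doc.start
            key = np.arange(self.L, dtype=np.int64) + delta[self.docid]
        self._key_cache[orientation] = key
        return key


class IrredundantSet:
    """The irredundant common patterns of a pair, with full occurrence lists.

    Array-backed: ``w_start``/``w_len`` give a representative occurrence of
    each distinct word in the index text and ``sa_lo``/``sa_hi`` its
    suffix-array interval, which enumerates every occurrence.  The
    :meth:`patterns` accessor materializes strings and occurrence records
    for inspection and testing.
    """

    def __init__(self, index: PairIndex, w_start, w_len, sa_lo, sa_hi):
        self.index = index
        self.w_start = np.asarray(w_start, dtype=np.int64)
        self.w_len = np.asarray(w_len, dtype=np.int64)
        self.sa_lo = np.asarray(sa_lo, dtype=np.int64)
        self.sa_hi = np.asarray(sa_hi, dtype=np.int64)
        occ1 = index._csum1[self.sa_hi] - index._csum1[self.sa_lo]
        occ2 = index._csum2[self.sa_hi] - index._csum2[self.sa_lo]
        self.occ1 = occ1.astype(np.int64)
        self.occ2 = occ2.astype(np.int64)
        self._pair_code_cache: tuple | None = None
        self._logp_cache: dict = {}

    def word_pair_codes(self):
        """Flattened per-word adjacent-pair codes (prev*4 + cur) plus the
        reduceat segment starts, for vectorized word-probability sums."""
        if self._pair_code_cache is None:
            text = self.index.text
            m = self.w_len - 1
            cs = np.concatenate(([0], np.cumsum(m)))
            total = int(cs[-1])
            idx = (
                np.arange(total, dtype=np.int64)
                - np.repeat(cs[:-1], m)
                + np.repeat(self.w_start, m)
            )
            pair_codes = text[idx] * 4 + text[idx + 1]
            self._pair_code_cache = (text[self.w_start], pair_codes, cs)
        return self._pair_code_cache

    def __len__(self) -> int:
        return len(self.w_len)

    def word(self, i: int) -> str:
        return self.index.word_at(int(self.w_start[i]), int(self.w_len[i]))

    def words(self) -> list[str]:
        return [self.word(i) for i in range(len(self))]

    def occurrence_positions(self, i: int) -> np.ndarray:
        """Global text positions of every occurrence of pattern i."""
        return np.sort(self.index.sa[self.sa_lo[i] : self.sa_hi[i]])

    def occurrences_of(self, i: int) -> list[Occurrence]:
        length = int(self.w_len[i])
        return [self.index.occurrence_at(int(g), length) for g in self.occurrence_positions(i)]

    def patterns(self) -> list[tuple[str, list[Occurrence]]]:
        return [(self.word(i), self.occurrences_of(i)) for i in range(len(self))]

    def first_occurrence_keys(self, orientation: int = 1) -> np.ndarray:
        """Earliest occurrence coordinate of each pattern for the priority rule."""
        key = self.index.priority_key(orientation)
        key_by_rank = np.concatenate(
            (key[self.index.sa], [np.iinfo(np.int64).max])
        )
        n = len(self)
        if n == 0:
            return np.empty(0, dtype=np.int64)
        bounds = np.empty(2 * n, dtype=np.int64)
        bounds[0::2] = self.sa_lo
        bounds[1::2] = self.sa_hi
        return np.minimum.reduceat(key_by_rank, bounds)[0::2]


def irredundant_common_patterns(
    r1: ReadSet, r2: ReadSet, transforms=TRANSFORMS
) -> IrredundantSet:
    """Extract the irredundant common patterns through the suffix index."""
    index = PairIndex(r1, r2, transforms)
    lam = _suffix.cross_set_lcp(index.sa, index.lcp, index.setflag)
    pos, length = _suffix.candidate_occurrences(lam, index.setflag)
    if len(pos) == 0:
        return IrredundantSet(index, [], [], [], [])
    lo, hi = _suffix.word_intervals(index.lcp, index.rank[pos], length)
    # deduplicate by word identity: same length + same suffix-array interval
    dedup_key = lo * np.int64(index.L + 1) + length
    _, first = np.unique(dedup_key, return_index=True)
    return IrredundantSet(index, pos[first], length[first], lo[first], hi[first])


def _all_shared_words(r1: ReadSet, r2: ReadSet, transforms) -> set[str]:
    subs: list[set[str]] = []
    for rs in (r1, r2):
        words: set[str] = set()
        for t in transforms:
            for read in rs.reads:
                s = _transform(read, t)
                n = len(s)
                for i in range(n):
                    for j in range(i + 1, n + 1):
                        w = s[i:j]
                        if "N" not in w:
                            words.add(w)
                        else:
                            break  # extending right keeps the N
        subs.append(words)
    return subs[0] & subs[1]


def common_patterns_bruteforce(
    r1: ReadSet, r2: ReadSet, transforms=("F",)
) -> dict[str, list[Occurrence]]:
    """Exhaustive shared-word enumeration (test oracle; tiny inputs only).

    Returns every word occurring in both sets, with its full occurrence
    list in both sets, deduplicated by word.
    """
    total = (r1.total_length + r2.total_length) * len(transforms)
    if total > _BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute-force enumeration is limited to {_BRUTE_FORCE_LIMIT} symbols "
            f"(got {total}); use irredundant_common_patterns instead"
        )
    transforms = tuple(t for t in TRANSFORMS if t in transforms)
    shared = _all_shared_words(r1, r2, transforms)
    out: dict[str, list[Occurrence]] = {}
    for w in sorted(shared):
        occs: list[Occurrence] = []
        for set_id, rs in ((1, r1), (2, r2)):
            for t in transforms:
                for idx, read in enumerate(rs.reads):
                    hay = _transform(read, t)
                    start = hay.find(w)
                    while start != -1:
                        occs.append(Occurrence(set_id, idx, t, start, len(w)))
                        start = hay.find(w, start + 1)
        out[w] = occs
    return out
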