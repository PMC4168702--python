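"""Order-0/1 Markov background models: word probabilities and expected counts.

The pattern dissimilarity weighs each pattern w by occ_w / E[occ_w], where
E[occ_w] = p_w * M * (beta - |w| + 1) for M reads of length beta: p_w is the
chance of seeing w at one site and M(beta-|w|+1) counts the possible sites.
Reads are short, so an order-1 chain is the default background (higher
orders overfit); order 0 (i.i.d.) is available for the D2-family nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkovModel",
    "ExpectationContext",
    "fit_markov",
    "word_probability",
    "expected_occurrences",
    "model_from_base_probs",
    "uniform_model",
    "gc_rich_model",
    "stationary_distribution",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


@dataclass
class MarkovModel:
    """Background model over ACGT.

    order 0: ``initial`` holds the i.i.d. base probabilities and
    ``transition`` is None.  order 1: ``initial`` is the start distribution
    (empirical symbol frequencies, not assumed stationary) and ``transition``
    the 4x4 row-stochastic matrix.
    """

    order: int
    initial: np.ndarray
    transition: np.ndarray | None = None
    trained_on: str = ""

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("only Markov orders 0 and 1 are supported")
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (4,):
            raise ValueError("initial distribution must have 4 entries")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if self.order == 1:
            if self.transition is None:
                raise ValueError("order-1 model requires a transition matrix")
            self.transition = np.asarray(self.transition, dtype=float)
            if self.transition.shape != (4, 4):
                raise ValueError("transition matrix must be 4x4")
            if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition rows must sum to 1")

    def log_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(log initial, log per-step table) with the order-0 model expressed
        as a chain whose rows all equal the base distribution."""
        with np.errstate(divide="ignore"):
            logpi = np.log(self.initial)
            if self.order == 0:
                logt = np.tile(logpi, (4, 1))
            else:
                logt = np.log(self.transition)
        return logpi, logt


@dataclass
class ExpectationContext:
    """Problem size for expected occurrence counts.

    ``transform_count`` scales the number of searched strings: 1 when only
    forward occurrences are counted, 4 when occurrences in the reverse,
    complement and reverse-complement are pooled in occ_w.
    """

    M: int
    beta: int
    transform_count: int = 1

    def __post_init__(self) -> None:
        if self.M < 1 or self.beta < 1 or self.transform_count < 1:
            raise ValueError("M, beta and transform_count must be >= 1")


_LUT = np.full(256, -1, dtype=np.int64)
for _ch, _c in _CODE.items():
    _LUT[ord(_ch)] = _c


def _pair_counts(reads) -> tuple[np.ndarray, np.ndarray]:
    # read separators and N positions code to -1 and break adjacency
    data = np.frombuffer("\n".join(reads).encode("ascii"), dtype=np.uint8)
    codes = _LUT[data]
    sym = np.bincount(codes[codes >= 0], minlength=4).astype(float)
    prev, cur = codes[:-1], codes[1:]
    ok = (prev >= 0) & (cur >= 0)
    pair = np.bincount(prev[ok] * 4 + cur[ok], minlength=16).astype(float).reshape(4, 4)
    return sym, pair


def fit_markov(rs, order: int = 1, pseudocount: float = 1.0) -> MarkovModel:
    """Fit a background model on the forward reads of a read set.

    Adjacent-pair counts never span read boundaries (or N positions).  The
    pseudocount (default 1) is added to every count cell so that p_w > 0 for
    every word, which the occ/E ratio requires.  A row with zero mass after
    smoothing falls back to the uniform distribution.
    """
    if order not in (0, 1):
        raise ValueError("only Markov orders 0 and 1 are supported")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    cache = getattr(rs, "_fit_cache", None)
    cache_key = (order, float(pseudocount))
    if cache is not None and cache_key in cache:
        return cache[cache_key]
    sym, pair = _pair_counts(rs.reads)
    if sym.sum() < 2:
        raise ValueError("need at least two ACGT symbols to fit a background model")
    pi = sym + pseudocount
    if pi.sum() == 0:
        pi = np.ones(4)
    pi = pi / pi.sum()
    if order == 0:
        model = MarkovModel(0, pi, trained_on=rs.label)
    else:
        trans = pair + pseudocount
        rowsum = trans.sum(axis=1, keepdims=True)
        uniform = np.full((4, 4), 0.25)
        with np.errstate(invalid="ignore", divide="ignore"):
            trans = np.where(rowsum > 0, trans / np.where(rowsum > 0, rowsum, 1.0), uniform)
        model = MarkovModel(1, pi, trans, trained_on=rs.label)
    if cache is not None:
        cache[cache_key] = model
    return model


def word_probability(m: MarkovModel, word: str) -> float:
    """p_w: order 0 -> prod pi(w_i); order 1 -> pi(w_1) prod A(w_i -> w_i+1)."""
    word = word.upper()
    if not word:
        raise ValueError("word must be non-empty")
    try:
        codes = [_CODE[ch] for ch in word]
    except KeyError as exc:
        raise ValueError(f"word contains a non-ACGT symbol: {word!r}") from exc
    p = float(m.initial[codes[0]])
    if m.order == 0:
        for c in codes[1:]:
            p *= float(m.initial[c])
    else:
        for a, b in zip(codes, codes[1:]):
            p *= float(m.transition[a, b])
    return p


def expected_occurrences(m: MarkovModel, word: str, ctx: ExpectationContext) -> float:
    """E[occ_w] = p_w * (M * transform_count) * (beta - |w| + 1)."""
    if len(word) > ctx.beta:
        raise ValueError(
            f"word of length {len(word)} cannot occur in reads of length {ctx.beta}"
        )
    return word_probability(m, word) * ctx.M * ctx.transform_count * (ctx.beta - len(word) + 1)


def model_from_base_probs(probs, label: str = "") -> MarkovModel:
    """Order-0 model from four base probabilities (A, C, G, T)."""
    return MarkovModel(0, np.asarray(probs, dtype=float), trained_on=label)


def uniform_model() -> MarkovModel:
    return model_from_base_probs([0.25] * 4, "uniform")


def gc_rich_model() -> MarkovModel:
    """The GC-rich i.i.d. background: p_A = p_T = 1/6, p_C = p_G = 1/3."""
    return model_from_base_probs([1 / 6, 1 / 3, 1 / 3, 1 / 6], "gc-rich")


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4-state chain (left eigenvector for 1)."""
    transition = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(transition.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()
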