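"""Underlying pattern selection: priority ranking and untied occurrences.

Every read position should contribute to the dissimilarity at most once.
The irredundant patterns are therefore ranked -- longer first, then less
probable under the background model, then earlier first occurrence -- and
scanned greedily: a pattern is kept only if, on the location vector holding
every cell claimed so far, it still owns at least one completely free
occurrence in *each* read set.  Accepted patterns claim the cells of all
their free (untied) occurrences, so the untied occurrences of the final
set are pairwise disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _suffix
from .markov import MarkovModel
from .patterns import IrredundantSet
from .readset import Occurrence

__all__ = [
    "PriorityKey",
    "LocationVector",
    "UnderlyingSet",
    "word_log_probabilities",
    "priority_order",
    "extract_underlying",
]

#: Decimal places kept when the priority rule compares log-probabilities.
#: Words whose probabilities are mathematically equal (permuted transition
#: multisets) must compare equal despite float summation-order noise; ties
#: then fall through to the first-occurrence rule.
PRIORITY_LOGP_DECIMALS = 9


@dataclass(frozen=True, order=True)
class PriorityKey:
    """Total order for the pattern priority rule (sorted ascending).

    Longer words first, then rarer under the null, then earlier first
    occurrence; the word itself is a final (in practice unreachable,
    because position+length determine the word) lexicographic tiebreak.
    """

    neg_length: int
    log_probability: float
    first_occurrence: int
    word: str = field(default="", compare=True)

    @classmethod
    def of(cls, word: str, log_probability: float, first_occurrence: int) -> "PriorityKey":
        return cls(
            -len(word),
            round(log_probability, PRIORITY_LOGP_DECIMALS),
            first_occurrence,
            word,
        )


def word_log_probabilities(
    irr: IrredundantSet, model: MarkovModel, quantize: bool = False
) -> np.ndarray:
    """log p_w for every pattern under the model, in one vectorized pass.

    Per-step log terms are summed over each word's adjacent pairs in word
    order (reduceat segments), matching a per-word evaluation.  Results are
    cached on the pattern set per model, since both the priority rule and
    the score need them.
    """
    n = len(irr)
    if n == 0:
        return np.empty(0, dtype=float)
    entry = irr._logp_cache.get(id(model))
    if entry is not None and entry[0] is model:
        lp = entry[1]
    else:
        first, pair_codes, cs = irr.word_pair_codes()
        logpi, logt = model.log_tables()
        step = np.append(logt.ravel()[pair_codes], 0.0)
        sums = np.add.reduceat(step, cs[:-1]) if len(step) > 1 else np.zeros(n)
        lp = logpi[first] + np.where(irr.w_len > 1, sums, 0.0)
        irr._logp_cache[id(model)] = (model, lp)
    if quantize:
        return np.round(lp, PRIORITY_LOGP_DECIMALS)
    return lp


def priority_order(
    irr: IrredundantSet, model: MarkovModel, orientation: int = 1
) -> np.ndarray:
    """Pattern indices sorted by the priority rule (highest priority first)."""
    lp = word_log_probabilities(irr, model, quantize=True)
    first = irr.first_occurrence_keys(orientation)
    return np.lexsort((first, lp, -irr.w_len))


@dataclass
class LocationVector:
    """Occupancy of every indexed position: 0 = free, otherwise 1 + the
    pattern index (into the IrredundantSet) whose untied occurrence claimed
    the cell."""

    gamma: np.ndarray
    irr: IrredundantSet

    def claimed_fraction(self) -> float:
        in_doc = self.irr.index.setflag >= 0
        return float((self.gamma[in_doc] != 0).mean())


class UnderlyingSet:
    """Accepted patterns with untied-occurrence and total-occurrence counts.

    ``orientation`` records which read set plays the role of "first" for
    the priority coordinate (1: the pair's native order; 2: swapped); the
    untied/occurrence counts themselves are always reported per set id.
    """

    def __init__(self, irr, orientation, pattern_ids, untied1, untied2, claim_pos, claim_pat):
        self.irr = irr
        self.orientation = orientation
        self.pattern_ids = np.asarray(pattern_ids, dtype=np.int64)
        self.untied1 = np.asarray(untied1, dtype=np.int64)
        self.untied2 = np.asarray(untied2, dtype=np.int64)
        self.occ1 = irr.occ1[self.pattern_ids]
        self.occ2 = irr.occ2[self.pattern_ids]
        self.w_len = irr.w_len[self.pattern_ids]
        self._claim_pos = claim_pos
        self._claim_pat = claim_pat

    def __len__(self) -> int:
        return len(self.pattern_ids)

    def words(self) -> list[str]:
        return [self.irr.word(int(i)) for i in self.pattern_ids]

    def untied_occurrences(self, which: int) -> list[Occurrence]:
        """Untied occurrences of the which-th accepted pattern."""
        p = self.pattern_ids[which]
        length = int(self.irr.w_len[p])
        sel = self._claim_pos[self._claim_pat == p]
        return [self.irr.index.occurrence_at(int(g), length) for g in np.sort(sel)]

    def patterns(self):
        """(word, untied occurrences in set 1, in set 2, (occ1, occ2)) per pattern."""
        out = []
        for i in range(len(self)):
            occs = self.untied_occurrences(i)
            out.append(
                (
                    self.irr.word(int(self.pattern_ids[i])),
                    [o for o in occs if o.set_id == 1],
                    [o for o in occs if o.set_id == 2],
                    (int(self.occ1[i]), int(self.occ2[i])),
                )
            )
        return out

    def mean_length(self) -> float:
        return float(self.w_len.mean()) if len(self) else 0.0


def extract_underlying(
    irr: IrredundantSet, model: MarkovModel, orientation: int = 1
) -> tuple[UnderlyingSet, LocationVector]:
    """Greedy location-vector pass in priority order (quadratic variant)."""
    if len(irr) == 0:
        empty = np.empty(0, dtype=np.int64)
        return (
            UnderlyingSet(irr, orientation, empty, empty, empty, empty, empty),
            LocationVector(np.zeros(irr.index.L, dtype=np.int64), irr),
        )
    order = priority_order(irr, model, orientation)
    key = irr.index.priority_key(orientation)
    accepted, untied1, untied2, gamma, claim_pos, claim_pat = _suffix.gamma_greedy(
        order,
        irr.sa_lo,
        irr.sa_hi,
        irr.w_len,
        irr.index.sa,
        key,
        irr.index.setflag,
    )
    # report accepted patterns in priority order for reproducible listings
    ids = order[accepted[order].astype(bool)]
    u = UnderlyingSet(irr, orientation, ids, untied1[ids], untied2[ids], claim_pos, claim_pat)
    return u, LocationVector(gamma, irr)
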