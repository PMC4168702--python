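"""The pattern-based dissimilarity between two read sets.

Score(R1, R2) sums, over the underlying patterns, the pattern length times
its untied occurrences in R1 times occ_w / E[occ_w], averaged over the
forward length |R1|.  The directed statistic

    under2(R1->R2) = log4(|R2|) / Score(R1, R2) - log4(|R1|)

is centred so that comparing a set against itself gives 0; the symmetric
dissimilarity is the mean of the two directions.  Smaller values mean more
similar read sets; very similar (but unequal) pairs can score below zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .markov import MarkovModel, fit_markov
from .patterns import IrredundantSet, irredundant_common_patterns
from .readset import TRANSFORMS, ReadSet
from .underlying import UnderlyingSet, extract_underlying, word_log_probabilities

__all__ = ["ComparisonResult", "score", "under2_asym", "under2"]


@dataclass
class ComparisonResult:
    """Both directed statistics plus the symmetric dissimilarity."""

    score_12: float
    score_21: float
    under2_12: float
    under2_21: float
    under2: float
    n_underlying_12: int = 0
    n_underlying_21: int = 0
    mean_pattern_length_12: float = 0.0
    mean_pattern_length_21: float = 0.0


def _directed_score(u: UnderlyingSet, model: MarkovModel, first_set: ReadSet,
                    transform_count: int) -> float:
    """Evaluate the Score sum for the set playing the 'first' role."""
    if len(u) == 0:
        return 0.0
    lp = word_log_probabilities(u.irr, model)[u.pattern_ids]
    lens = u.w_len
    # possible occurrence sites of each word in the first set
    read_lens = np.sort([len(r) for r in first_set.reads])
    suffix_tot = np.concatenate((np.cumsum(read_lens[::-1])[::-1], [0]))
    k = np.searchsorted(read_lens, lens)  # reads shorter than the word
    n_ge = len(read_lens) - k
    sites = (suffix_tot[k] - n_ge * (lens - 1)) * transform_count
    untied = u.untied1 if first_set is u.irr.index.r1 else u.untied2
    occ = u.occ1 if first_set is u.irr.index.r1 else u.occ2
    with np.errstate(over="ignore", divide="ignore"):
        expectation = np.exp(lp) * sites
        ratio = occ / expectation
    if not np.all(np.isfinite(ratio)):
        warnings.warn(
            "expected occurrence count underflowed for some pattern; "
            "its occ/E ratio is infinite", RuntimeWarning,
        )
    return float(np.sum(lens * untied * ratio) / first_set.total_length)


def score(r1: ReadSet, r2: ReadSet, u: UnderlyingSet, m: MarkovModel) -> float:
    """Score(R1, R2) from an UnderlyingSet extracted for this orientation."""
    if u.irr.index.r1 is not r1 or u.irr.index.r2 is not r2:
        raise ValueError("underlying set was not extracted from (r1, r2)")
    first = r1 if u.orientation == 1 else r2
    return _directed_score(u, m, first, len(u.irr.index.transforms))


def _log4(x: float) -> float:
    return math.log(x) / math.log(4.0)


def _asym_from_score(s: float, first: ReadSet, second: ReadSet) -> float:
    if s == 0.0:
        if sorted(first.reads) != sorted(second.reads):
            warnings.warn(
                f"no shared pattern signal between {first.label!r} and "
                f"{second.label!r}; directed statistic is +inf", RuntimeWarning,
            )
        return math.inf
    return _log4(second.total_length) / s - _log4(first.total_length)


def under2(
    r1: ReadSet,
    r2: ReadSet,
    transforms=TRANSFORMS,
    order: int = 1,
    pseudocount: float = 1.0,
    model_scope: str = "first",
) -> ComparisonResult:
    """Symmetric pattern dissimilarity between two read sets.

    The background model for each direction is fitted on the set whose
    positions are being scored (``model_scope="first"``) or on both sets
    pooled (``"pooled"``).  Identical read multisets short-circuit to 0.
    Arguments are canonicalized so that swapping them returns the exact
    same numbers with the two directions mirrored.
    """
    if sorted(r1.reads) == sorted(r2.reads):
        return ComparisonResult(1.0, 1.0, 0.0, 0.0, 0.0)
    if model_scope not in ("first", "pooled"):
        raise ValueError("model_scope must be 'first' or 'pooled'")
    if (r2.label, r2.reads) < (r1.label, r1.reads):
        res = under2(r2, r1, transforms, order, pseudocount, model_scope)
        return ComparisonResult(
            score_12=res.score_21,
            score_21=res.score_12,
            under2_12=res.under2_21,
            under2_21=res.under2_12,
            under2=res.under2,
            n_underlying_12=res.n_underlying_21,
            n_underlying_21=res.n_underlying_12,
            mean_pattern_length_12=res.mean_pattern_length_21,
            mean_pattern_length_21=res.mean_pattern_length_12,
        )
    irr = irredundant_common_patterns(r1, r2, transforms)
    tc = len(irr.index.transforms)
    if model_scope == "pooled":
        pooled = ReadSet(f"{r1.label}+{r2.label}", r1.reads + r2.reads)
        m1 = m2 = fit_markov(pooled, order, pseudocount)
    else:
        m1 = fit_markov(r1, order, pseudocount)
        m2 = fit_markov(r2, order, pseudocount)
    u12, _ = extract_underlying(irr, m1, orientation=1)
    u21, _ = extract_underlying(irr, m2, orientation=2)
    s12 = _directed_score(u12, m1, r1, tc)
    s21 = _directed_score(u21, m2, r2, tc)
    a12 = _asym_from_score(s12, r1, r2)
    a21 = _asym_from_score(s21, r2, r1)
    return ComparisonResult(
        score_12=s12,
        score_21=s21,
        under2_12=a12,
        under2_21=a21,
        under2=(a12 + a21) / 2.0,
        n_underlying_12=len(u12),
        n_underlying_21=len(u21),
        mean_pattern_length_12=u12.mean_length(),
        mean_pattern_length_21=u21.mean_length(),
    )


def under2_asym(r1: ReadSet, r2: ReadSet, **kwargs) -> float:
    """Directed statistic under2(R1 -> R2)."""
    return under2(r1, r2, **kwargs).under2_12
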