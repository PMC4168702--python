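"""Independent brute-force oracles used by the tests.

Everything here works directly from the definitions (exhaustive substring
enumeration, literal containment checks, a literal location-vector pass,
explicit bipartition sets) and never touches the suffix-array machinery it
is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np

from under2.markov import word_probability
from under2.patterns import common_patterns_bruteforce
from under2.readset import TRANSFORMS
from under2.underlying import PRIORITY_LOGP_DECIMALS

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_irredundant(r1, r2, transforms=("F",)):
    """Literal Definition-1 filter over the exhaustive shared-word list."""
    shared = common_patterns_bruteforce(r1, r2, transforms)
    per_doc: dict[tuple, list[tuple[int, int]]] = {}
    for w, occs in shared.items():
        for o in occs:
            per_doc.setdefault((o.set_id, o.read_index, o.transform), []).append(
                (o.offset, o.offset + o.length)
            )
    out = {}
    for w, occs in shared.items():
        for o in occs:
            l, r = o.offset, o.offset + o.length
            covered = any(
                l2 <= l and r2 >= r and (r2 - l2) > (r - l)
                for (l2, r2) in per_doc[(o.set_id, o.read_index, o.transform)]
            )
            if not covered:
                out[w] = sorted(occs)
                break
    return out


def _doc_layout(r1, r2, transforms, swap):
    """Global start offset of every document in priority-coordinate order."""
    sets = [(2, r2), (1, r1)] if swap else [(1, r1), (2, r2)]
    start, pos = {}, 0
    for t in [t for t in TRANSFORMS if t in transforms]:
        for set_id, rs in sets:
            for i, read in enumerate(rs.reads):
                start[(set_id, i, t)] = pos
                pos += len(read)
    return start, pos


def word_log_prob(model, word):
    """log p_w summed over the word's transition terms via numpy reduce,
    then quantized exactly like the priority rule."""
    logpi = np.log(model.initial)
    first = logpi[_CODE[word[0]]]
    if len(word) == 1:
        return round(float(first), PRIORITY_LOGP_DECIMALS)
    if model.order == 0:
        terms = np.array([logpi[_CODE[c]] for c in word[1:]])
    else:
        logt = np.log(model.transition)
        terms = np.array([logt[_CODE[a], _CODE[b]] for a, b in zip(word, word[1:])])
    return round(float(first + np.add.reduce(terms)), PRIORITY_LOGP_DECIMALS)


def brute_underlying(r1, r2, model, transforms=("F",), swap=False):
    """Literal greedy location-vector pass over the Definition-1 output.

    Returns {word: (untied occurrences in set 1, in set 2)} for the
    accepted patterns, plus the final free/claimed vector.
    """
    irr = brute_irredundant(r1, r2, transforms)
    start, L = _doc_layout(r1, r2, transforms, swap)
    gamma = np.zeros(L, dtype=int)

    def coord(o):
        return start[(o.set_id, o.read_index, o.transform)] + o.offset

    ranked = sorted(
        irr.items(),
        key=lambda kv: (
            -len(kv[0]),
            word_log_prob(model, kv[0]),
            min(coord(o) for o in kv[1]),
            kv[0],
        ),
    )
    accepted = {}
    for w, occs in ranked:
        claims, untied = [], {1: 0, 2: 0}
        for o in sorted(occs, key=coord):
            g = coord(o)
            if not gamma[g : g + o.length].any():
                gamma[g : g + o.length] = 1
                claims.append((g, o.length))
                untied[o.set_id] += 1
        if untied[1] > 0 and untied[2] > 0:
            accepted[w] = (untied[1], untied[2])
        else:
            for g, ln in claims:
                gamma[g : g + ln] = 0
    return accepted, gamma, irr


def direct_score(r1, r2, accepted, irr, model, transforms=("F",)):
    """Direct evaluation of the Score sum from brute-force quantities."""
    tc = len(transforms)
    total = 0.0
    for w, (u1, _u2) in accepted.items():
        occ1 = sum(1 for o in irr[w] if o.set_id == 1)
        sites = sum(max(0, len(r) - len(w) + 1) for r in r1.reads) * tc
        expectation = word_probability(model, w) * sites
        total += len(w) * u1 * occ1 / expectation
    return total / r1.total_length


def tree_bipartitions(tree):
    """Non-trivial bipartitions of a dendropy tree as frozensets of labels."""
    labels = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    bips = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.is_leaf():
            continue
        below = frozenset(
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        )
        if 1 < len(below) < len(labels) - 1:
            bips.add(min(below, labels - below, key=sorted))
    return bips


def brute_rf(t1, t2):
    """Robinson-Foulds via explicit bipartition-set comparison."""
    return len(tree_bipartitions(t1) ^ tree_bipartitions(t2))
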