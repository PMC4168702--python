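"""Suffix-array machinery behind the pattern extraction.

The generalized index concatenates every document (each transform of each
read of both sets) with unique sentinel codes in between, builds a suffix
array by prefix doubling (numpy), the LCP array (Kasai), and then derives:

* per-position cross-set matching statistics lam(i) = length of the longest
  prefix of the suffix at i that also occurs somewhere in the other set;
* the candidate occurrences that no longer shared word covers;
* suffix-array intervals (= full occurrence lists) for each candidate word;
* the greedy location-vector pass that selects untied occurrences.

Sequential kernels are JIT-compiled with numba; everything else is numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "suffix_array",
    "lcp_array",
    "cross_set_lcp",
    "candidate_occurrences",
    "word_intervals",
    "gamma_greedy",
]


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence via prefix doubling.

    Sentinel codes must be unique so that suffix comparisons never cross a
    document boundary.
    """
    n = len(text)
    rank = np.asarray(text, dtype=np.int64)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    k = 1
    while True:
        key2 = np.zeros(n, dtype=np.int64)
        key2[: n - k] = rank[k:] + 1  # suffixes past the end sort first
        combined = rank * np.int64(n + 1) + key2  # rank, key2 < n+1: no overflow
        order = np.argsort(combined)
        combined = combined[order]
        diff = np.ones(n, dtype=bool)
        diff[1:] = combined[1:] != combined[:-1]
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(diff) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


@njit(cache=True)
def _kasai(text, sa, rank):
    n = sa.shape[0]
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def lcp_array(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """lcp[r] = longest common prefix of the suffixes at ranks r-1 and r."""
    rank = np.empty_like(sa)
    rank[sa] = np.arange(len(sa), dtype=np.int64)
    return _kasai(np.ascontiguousarray(text), sa, rank)


@njit(cache=True)
def cross_set_lcp(sa, lcp, setflag):
    """lam[i]: longest prefix of suffix i occurring in the other set.

    ``setflag`` holds 0/1 for positions of the two sets and -1 for
    sentinels.  Two sweeps over suffix-array order, carrying the running
    minimum LCP to the nearest suffix of each set.
    """
    n = sa.shape[0]
    lam = np.zeros(n, dtype=np.int64)
    NONE = np.int64(-1)
    BIG = np.int64(1) << 60
    b0 = NONE
    b1 = NONE
    for r in range(n):
        if r > 0:
            l = lcp[r]
            if b0 != NONE and l < b0:
                b0 = l
            if b1 != NONE and l < b1:
                b1 = l
        p = sa[r]
        s = setflag[p]
        if s == 0:
            if b1 > lam[p]:
                lam[p] = b1
            b0 = BIG
        elif s == 1:
            if b0 > lam[p]:
                lam[p] = b0
            b1 = BIG
    b0 = NONE
    b1 = NONE
    for r in range(n - 1, -1, -1):
        if r < n - 1:
            l = lcp[r + 1]
            if b0 != NONE and l < b0:
                b0 = l
            if b1 != NONE and l < b1:
                b1 = l
        p = sa[r]
        s = setflag[p]
        if s == 0:
            if b1 > lam[p]:
                lam[p] = b1
            b0 = BIG
        elif s == 1:
            if b0 > lam[p]:
                lam[p] = b0
            b1 = BIG
    return lam


def candidate_occurrences(lam: np.ndarray, setflag: np.ndarray):
    """Positions whose maximal shared prefix no longer shared word covers.

    An occurrence [i, i + lam(i)) cannot be extended to the right (lam is
    maximal) and cannot be extended to the left exactly when i starts a
    document or lam(i-1) <= lam(i); shared words are substring-closed, so
    these one-step checks rule out every longer covering occurrence.
    """
    in_doc = setflag >= 0
    prev_lam = np.concatenate(([np.int64(0)], lam[:-1]))
    prev_in_doc = np.concatenate(([False], in_doc[:-1]))
    doc_start = ~prev_in_doc
    keep = in_doc & (lam >= 1) & (doc_start | (prev_lam <= lam))
    pos = np.nonzero(keep)[0].astype(np.int64)
    return pos, lam[pos]


@njit(cache=True)
def _uf_find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


def word_intervals(lcp, qrank, qlen):
    """Suffix-array interval [lo, hi) of suffixes sharing the first qlen
    symbols with the suffix at rank qrank, for a batch of queries.

    Offline union-find: adjacent ranks are merged in decreasing LCP order
    while queries are answered in decreasing length order.
    """
    edge_order = np.argsort(-lcp[1:])
    query_order = np.argsort(-qlen)
    return _word_intervals(lcp, qrank, qlen, edge_order, query_order)


@njit(cache=True)
def _word_intervals(lcp, qrank, qlen, edge_order, query_order):
    n = lcp.shape[0]
    nq = qrank.shape[0]
    parent = np.arange(n)
    lo = np.arange(n)
    hi = np.arange(n) + 1
    out_lo = np.empty(nq, dtype=np.int64)
    out_hi = np.empty(nq, dtype=np.int64)
    ei = 0
    ne = n - 1
    for t in range(nq):
        q = query_order[t]
        threshold = qlen[q]
        while ei < ne:
            r = edge_order[ei] + 1
            if lcp[r] < threshold:
                break
            a = _uf_find(parent, r - 1)
            b = _uf_find(parent, r)
            if a != b:
                parent[b] = a
                if lo[b] < lo[a]:
                    lo[a] = lo[b]
                if hi[b] > hi[a]:
                    hi[a] = hi[b]
            ei += 1
        root = _uf_find(parent, qrank[q])
        out_lo[q] = lo[root]
        out_hi[q] = hi[root]
    return out_lo, out_hi


@njit(cache=True)
def gamma_greedy(order, sa_lo, sa_hi, w_len, sa, key, setflag):
    """Greedy untied-occurrence selection over the location vector.

    Patterns arrive in priority order.  For each, occurrences are visited in
    ascending coordinate ``key``; an occurrence is untied iff every one of
    its cells is still free.  The pattern is accepted iff it has at least
    one untied occurrence in each set, in which case all its untied
    occurrences claim their cells; otherwise its tentative claims roll back.

    Returns (accepted mask, untied counts per set, gamma, untied occurrence
    positions, their pattern ids).
    """
    L = setflag.shape[0]
    npat = sa_lo.shape[0]
    gamma = np.zeros(L, dtype=np.int64)
    accepted = np.zeros(npat, dtype=np.uint8)
    untied1 = np.zeros(npat, dtype=np.int64)
    untied2 = np.zeros(npat, dtype=np.int64)
    max_occ = 0
    for p in range(npat):
        c = sa_hi[p] - sa_lo[p]
        if c > max_occ:
            max_occ = c
    scratch = np.empty(max_occ, dtype=np.int64)
    total_claims = 0
    claim_pos = np.empty(L, dtype=np.int64)
    claim_pat = np.empty(L, dtype=np.int64)
    occ_buf = np.empty(max_occ, dtype=np.int64)
    key_buf = np.empty(max_occ, dtype=np.int64)
    for t in range(order.shape[0]):
        p = order[t]
        length = w_len[p]
        nocc = sa_hi[p] - sa_lo[p]
        for i in range(nocc):
            g = sa[sa_lo[p] + i]
            k = key[g]
            # insertion sort by coordinate (occurrence lists are short)
            j = i
            while j > 0 and key_buf[j - 1] > k:
                key_buf[j] = key_buf[j - 1]
                occ_buf[j] = occ_buf[j - 1]
                j -= 1
            key_buf[j] = k
            occ_buf[j] = g
        cnt = 0
        u1 = 0
        u2 = 0
        for i in range(nocc):
            g = occ_buf[i]
            free = True
            for c in range(g, g + length):
                if gamma[c] != 0:
                    free = False
                    break
            if free:
                for c in range(g, g + length):
                    gamma[c] = p + 1
                scratch[cnt] = g
                cnt += 1
                if setflag[g] == 0:
                    u1 += 1
                else:
                    u2 += 1
        if u1 > 0 and u2 > 0:
            accepted[p] = 1
            untied1[p] = u1
            untied2[p] = u2
            for i in range(cnt):
                claim_pos[total_claims] = scratch[i]
                claim_pat[total_claims] = p
                total_claims += 1
        else:
            for i in range(cnt):
                g = scratch[i]
                for c in range(g, g + length):
                    gamma[c] = 0
    return (
        accepted,
        untied1,
        untied2,
        gamma,
        claim_pos[:total_claims].copy(),
        claim_pat[:total_claims].copy(),
    )
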