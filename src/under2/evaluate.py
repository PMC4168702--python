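"""Benchmark scoring: PPV, distance matrices, NJ/UPGMA trees, RF distance.

The positive-predictive-value protocol scores every within-set pair of the
positive and of the negative collection, merges the two score lists, and
reports the fraction of positive pairs among the best floor(total/2)
entries: 1 means perfect separation, 0.5 no statistical power.  Distance
matrices feed neighbor joining (scikit-bio) and UPGMA (SciPy average
linkage), and reconstructed trees are scored against a reference with the
Robinson-Foulds bipartition distance (dendropy).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .dissimilarity import under2
from .dtype import DTYPE_STATS, dtype_dissimilarity
from .io import DistanceMatrix
from .simulate import SimulationConfig, build_experiment

__all__ = [
    "ScoredPairs",
    "ppv",
    "pairwise_matrix",
    "nj",
    "upgma",
    "robinson_foulds",
    "run_benchmark",
    "ALL_STATS",
]

ALL_STATS = ("under2",) + DTYPE_STATS

#: Ranking direction per statistic: True when smaller = more similar.
_IS_DISSIMILARITY = {
    "under2": True,
    "d2": True,
    "d2s": True,
    "d2star": True,
    "D2": False,  # raw inner products, if scored directly
    "D2S": False,
    "D2STAR": False,
}


@dataclass
class ScoredPairs:
    """All within-positive-set and within-negative-set pair scores."""

    positive_scores: list[float]
    negative_scores: list[float]
    orientation: str = "dissimilarity"  # or "similarity"

    def __post_init__(self) -> None:
        if self.orientation not in ("dissimilarity", "similarity"):
            raise ValueError("orientation must be 'dissimilarity' or 'similarity'")
        if not self.positive_scores or not self.negative_scores:
            raise ValueError("both score lists must be non-empty")


def ppv(sp: ScoredPairs) -> float:
    """Fraction of positive pairs in the top half of the merged ranking.

    Scores are oriented so that "better" means more similar; the top half
    holds the best floor(total/2) entries.  A tie group straddling the cut
    contributes its positives proportionally (midrank share), which keeps
    the value deterministic.
    """
    pos = np.asarray(sp.positive_scores, dtype=float)
    neg = np.asarray(sp.negative_scores, dtype=float)
    scores = np.concatenate((pos, neg))
    if sp.orientation == "similarity":
        scores = -scores
    is_pos = np.concatenate((np.ones(len(pos), bool), np.zeros(len(neg), bool)))
    half = len(scores) // 2
    if half == 0:
        raise ValueError("need at least two pair scores")
    order = np.argsort(scores, kind="mergesort")
    scores = scores[order]
    is_pos = is_pos[order]
    credited = 0.0
    used = 0
    i = 0
    n = len(scores)
    while i < n and used < half:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        g = j - i
        p = int(is_pos[i:j].sum())
        room = half - used
        if g <= room:
            credited += p
            used += g
        else:
            credited += p * room / g
            used = half
        i = j
    return credited / half


def _pair_score(r1, r2, stat: str, params: dict) -> float:
    if stat == "under2":
        return under2(r1, r2, **params).under2
    if stat in DTYPE_STATS:
        return dtype_dissimilarity(r1, r2, stat=stat, **params)
    raise ValueError(f"unknown statistic {stat!r}; choose from {ALL_STATS}")


def pairwise_matrix(readsets, stat: str = "under2", params: dict | None = None) -> DistanceMatrix:
    """Symmetric dissimilarity matrix over a list of read sets."""
    readsets = list(readsets)
    if len(readsets) < 2:
        raise ValueError("need at least two read sets")
    params = dict(params or {})
    n = len(readsets)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = _pair_score(readsets[i], readsets[j], stat, params)
        values[i, j] = values[j, i] = d
    return DistanceMatrix([rs.label for rs in readsets], values)


def _as_nonnegative(m: DistanceMatrix) -> np.ndarray:
    """Uniformly shift off-diagonal entries so the minimum is 0.

    NJ and UPGMA topologies are invariant under adding a constant to every
    off-diagonal entry, so the shift is a safe gauge for consumers that
    require non-negative dissimilarities.
    """
    v = m.values.copy()
    off = ~np.eye(len(m), dtype=bool)
    low = v[off].min()
    if low < 0:
        v[off] -= low
    return v


def nj(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree."""
    if len(m) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    skdm = _SkbioDM(_as_nonnegative(m), ids=m.labels)
    newick = str(_skbio_nj(skdm))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def upgma(m: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration; returns a rooted ultrametric tree."""
    if len(m) < 3:
        raise ValueError("UPGMA needs at least three taxa")
    z = linkage(squareform(_as_nonnegative(m), checks=False), method="average")
    n = len(m)
    tns = dendropy.TaxonNamespace(m.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    heights = []
    for label in m.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
        heights.append(0.0)
    for a, b, dist, _size in z:
        parent = dendropy.Node()
        h = dist / 2.0
        for child_idx in (int(a), int(b)):
            child = nodes[child_idx]
            child.edge.length = h - heights[child_idx]
            parent.add_child(child)
        nodes.append(parent)
        heights.append(h)
    tree.seed_node = nodes[-1]
    tree.is_rooted = True
    return tree


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric difference of the non-trivial bipartition sets.

    Trees are compared unrooted; 0 means isomorphic and 2n - 6 bounds the
    distance for two binary trees on n leaves.
    """
    labels1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    labels2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if labels1 != labels2:
        raise ValueError(
            f"trees have different leaf sets: {sorted(labels1 ^ labels2)} differ"
        )
    if len(labels1) < 3:
        raise ValueError("Robinson-Foulds needs at least three leaves")
    tns = dendropy.TaxonNamespace(sorted(labels1))
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    for t in (a, b):
        t.is_rooted = False
        t.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def scored_pairs_for(readsets_pos, readsets_neg, stat: str, params: dict | None = None) -> ScoredPairs:
    """Score all within-positive and within-negative pairs with one statistic."""
    params = dict(params or {})
    pos = [
        _pair_score(a, b, stat, params) for a, b in combinations(readsets_pos, 2)
    ]
    neg = [
        _pair_score(a, b, stat, params) for a, b in combinations(readsets_neg, 2)
    ]
    orientation = "dissimilarity" if _IS_DISSIMILARITY.get(stat, True) else "similarity"
    return ScoredPairs(pos, neg, orientation)


def run_benchmark(
    cfg: SimulationConfig,
    stats=ALL_STATS,
    n_pos: int = 20,
    n_neg: int = 20,
    n_replicates: int = 5,
    stat_params: dict | None = None,
):
    """PPV of each statistic over independently seeded replicates.

    Returns a list of row dicts (replicate, seed, statistic, ppv) plus a
    final mean row per statistic.
    """
    stat_params = stat_params or {}
    rows = []
    per_stat: dict[str, list[float]] = {s: [] for s in stats}
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    for rep, seed in enumerate(rep_seeds):
        rep_cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
        positives, negatives = build_experiment(rep_cfg, n_pos, n_neg)
        for stat in stats:
            sp = scored_pairs_for(positives, negatives, stat, stat_params.get(stat))
            value = ppv(sp)
            per_stat[stat].append(value)
            rows.append({"replicate": rep, "seed": seed, "statistic": stat, "ppv": value})
    for stat in stats:
        rows.append(
            {
                "replicate": "mean",
                "seed": cfg.seed,
                "statistic": stat,
                "ppv": float(np.mean(per_stat[stat])),
            }
        )
    return rows
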