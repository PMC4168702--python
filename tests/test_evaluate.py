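import numpy as np
import pytest

import dendropy

from under2.io import DistanceMatrix, read_newick
from under2.dtype import dtype_dissimilarity
from under2.evaluate import (
    ScoredPairs,
    nj,
    pairwise_matrix,
    ppv,
    robinson_foulds,
    run_benchmark,
    upgma,
)
from under2.readset import ReadSet
from under2.simulate import SimulationConfig

from conftest import random_readset
from oracles import brute_rf, tree_bipartitions


class TestPPV:
    def test_perfect_separation(self):
        sp = ScoredPairs([0.1, 0.2, 0.15], [0.6, 0.7, 0.8], "dissimilarity")
        assert ppv(sp) == 1.0

    def test_all_tied_scores_give_half(self):
        sp = ScoredPairs([1.0] * 10, [1.0] * 10, "dissimilarity")
        assert ppv(sp) == pytest.approx(0.5)

    def test_small_example_by_direct_ranking(self):
        sp = ScoredPairs([0.1, 0.2], [0.3, 0.4], "dissimilarity")
        assert ppv(sp) == 1.0

    def test_similarity_orientation_flips_ranking(self):
        sp = ScoredPairs([0.9, 0.8], [0.1, 0.2], "similarity")
        assert ppv(sp) == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        pos = rng.normal(size=30).tolist()
        neg = rng.normal(size=40).tolist()
        base = ppv(ScoredPairs(pos, neg, "dissimilarity"))
        warped = ppv(
            ScoredPairs(
                [np.arctan(x) * 3 + 7 for x in pos],
                [np.arctan(x) * 3 + 7 for x in neg],
                "dissimilarity",
            )
        )
        assert warped == pytest.approx(base)
        assert 0.0 <= base <= 1.0

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            ScoredPairs([], [0.1], "dissimilarity")


class TestPairwiseMatrix:
    def test_duplicate_sets_have_zero_distance(self):
        rs = ReadSet("a", ["ACGTACGTAC", "TTGGCCAATT"])
        dup = ReadSet("b", list(rs.reads))
        other = ReadSet("c", ["GGGGGCCCCC", "ATATATATAT"])
        m = pairwise_matrix([rs, dup, other], "under2")
        assert m[("a", "b")] == 0.0
        assert m.values.shape == (3, 3)

    def test_matches_elementwise_recomputation(self, rng):
        sets = [random_readset(rng, f"s{i}", (3, 5), (20, 30)) for i in range(3)]
        m = pairwise_matrix(sets, "d2s", {"k": 3})
        for i in range(3):
            for j in range(i + 1, 3):
                direct = dtype_dissimilarity(sets[i], sets[j], "d2s", k=3)
                assert m.values[i, j] == pytest.approx(direct)


class TestTreeMethods:
    def test_nj_recovers_additive_tree(self):
        # distances generated from ((a:1,b:2):1,(c:3,d:4):1)
        m = DistanceMatrix(
            ["a", "b", "c", "d"],
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        t = nj(m)
        assert tree_bipartitions(t) == {frozenset({"a", "b"})} or tree_bipartitions(
            t
        ) == {frozenset({"c", "d"})}
        # branch lengths recovered exactly on additive input
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(1.0, abs=1e-9)
        assert lengths["d"] == pytest.approx(4.0, abs=1e-9)

    def test_upgma_reproduces_ultrametric_distances(self):
        # ultrametric: cophenetic heights 2 (a,b), 4 (ab,c), 6 (abc,d)
        m = DistanceMatrix(
            ["a", "b", "c", "d"],
            [[0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]],
        )
        t = upgma(m)
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for (x, y), d in {
            ("a", "b"): 2.0, ("a", "c"): 4.0, ("b", "c"): 4.0, ("a", "d"): 6.0,
        }.items():
            assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(d, abs=1e-9)

    def test_three_equidistant_taxa(self):
        m = DistanceMatrix(["a", "b", "c"], [[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        t = upgma(m)
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        d = [
            pdm.patristic_distance(taxa[x], taxa[y])
            for x, y in (("a", "b"), ("a", "c"), ("b", "c"))
        ]
        assert np.allclose(d, 2.0, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], [[0, 1, 2], [1.1, 0, 1], [2, 1, 0]])


class TestRobinsonFoulds:
    def test_identical_trees_are_isomorphic(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((b,a),(d,c));")
        assert robinson_foulds(t1, t2) == 0

    def test_conflicting_quartets_reach_the_bound(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        assert robinson_foulds(t1, t2) == 2  # 2n - 6 for n = 4

    def test_leaf_set_mismatch_is_error(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,b),(c,e));")
        with pytest.raises(ValueError, match="leaf sets"):
            robinson_foulds(t1, t2)

    def test_matches_bipartition_enumeration_on_random_trees(self):
        import random

        rnd = random.Random(11)
        for trial in range(10):
            tns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
            t1 = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=8, rng=rnd
            )
            t2 = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=8, rng=rnd
            )
            got = robinson_foulds(t1, t2)
            assert got == brute_rf(t1, t2)
            assert robinson_foulds(t1, t1) == 0
            assert got <= 2 * 8 - 6


class TestBenchmarkRunner:
    def test_null_benchmark_is_calibrated_and_deterministic(self):
        cfg = SimulationConfig(N=500, lam=0.0, gamma=2.0, beta=100, seed=21)
        rows1 = run_benchmark(cfg, ("d2",), n_pos=5, n_neg=5, n_replicates=2)
        rows2 = run_benchmark(cfg, ("d2",), n_pos=5, n_neg=5, n_replicates=2)
        assert rows1 == rows2
        mean = [r for r in rows1 if r["replicate"] == "mean"][0]["ppv"]
        assert 0.0 <= mean <= 1.0
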