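import numpy as np
import pytest

from under2.io import SequenceRecord, write_sequences
from under2.simulate import (
    DEFAULT_MOTIFS,
    SimulationConfig,
    build_experiment,
    evolve_genomes,
    generate_background,
    implant_motifs,
    sample_reads,
    _motif_variants,
)


class TestBackground:
    def test_uniform_base_frequencies(self, rng):
        cfg = SimulationConfig(N=100_000)
        seq = generate_background(cfg, rng)
        freqs = np.array([seq.count(b) for b in "ACGT"]) / len(seq)
        assert np.allclose(freqs, 0.25, atol=0.01)

    def test_gc_rich_frequencies(self, rng):
        cfg = SimulationConfig(N=100_000, background="gcrich")
        seq = generate_background(cfg, rng)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 2 / 3) < 0.01

    def test_fasta_window_forced(self, tmp_path, rng):
        ref = "".join(rng.choice(list("ACGT"), 1000))
        p = tmp_path / "bg.fasta"
        write_sequences([SequenceRecord("chr", ref)], p)
        cfg = SimulationConfig(N=1000, background="fasta-window", fasta_path=str(p))
        assert generate_background(cfg, rng) == ref

    def test_fasta_window_too_short_is_error(self, tmp_path, rng):
        p = tmp_path / "bg.fasta"
        write_sequences([SequenceRecord("chr", "ACGT" * 10)], p)
        cfg = SimulationConfig(N=1000, background="fasta-window", fasta_path=str(p))
        with pytest.raises(ValueError, match="at least"):
            generate_background(cfg, rng)


class TestImplantation:
    def test_zero_intensity_is_identity(self, rng):
        cfg = SimulationConfig(N=2000, lam=0.0, model="CM")
        seq = generate_background(cfg, rng)
        assert implant_motifs(seq, cfg, rng) == seq

    def test_full_intensity_tiles_the_motif(self, rng):
        cfg = SimulationConfig(N=10, lam=1.0, model="CM", motifs=("ACGTC",), beta=10)
        seq = "T" * 10
        assert implant_motifs(seq, cfg, rng) == "ACGTCACGTC"

    def test_length_preserved(self, rng):
        for model in ("CM", "SMM", "FMM"):
            cfg = SimulationConfig(N=5000, lam=0.05, model=model)
            seq = generate_background(cfg, rng)
            assert len(implant_motifs(seq, cfg, rng)) == len(seq)

    def test_variant_sets(self):
        assert len(_motif_variants(SimulationConfig(model="CM"))) == 1
        assert len(_motif_variants(SimulationConfig(model="SMM"))) == 10
        assert len(_motif_variants(SimulationConfig(model="FMM"))) == 15
        assert sorted(len(m) for m in DEFAULT_MOTIFS) == [4, 5, 5, 6, 6]

    def test_smm_variants_equally_likely(self, rng):
        """Each motif-or-reverse-complement variant lands in proportion
        1/10 of implants (Monte-Carlo over a megabase).

        Motifs are chosen so that no variant is a substring of another and
        all stand out against the all-T background.
        """
        motifs = ("ACGG", "CAGGT", "GTCCA", "CCATAG", "GGTATC")
        cfg = SimulationConfig(N=1_000_000, lam=0.01, model="SMM", motifs=motifs)
        variants = _motif_variants(cfg)
        assert len(set(variants)) == 10
        seq = implant_motifs("T" * cfg.N, cfg, rng)
        counts = np.array([seq.count(v) for v in variants], dtype=float)
        share = counts / counts.sum()
        se = np.sqrt(0.1 * 0.9 / counts.sum())
        assert np.all(np.abs(share - 0.1) < 4 * se + 0.01)


class TestReadSampling:
    def test_read_count_from_coverage(self, rng):
        cfg = SimulationConfig(N=1000, gamma=5.0, beta=200)
        rs = sample_reads("ACGT" * 250, cfg, rng)
        assert rs.n_reads == 25 and all(len(r) == 200 for r in rs.reads)

    def test_error_free_reads_are_substrings(self, rng):
        cfg = SimulationConfig(N=1000, gamma=2.0, beta=50)
        seq = generate_background(cfg, rng)
        rs = sample_reads(seq, cfg, rng)
        assert all(r in seq for r in rs.reads)

    def test_substitution_rate(self, rng):
        """Mean mismatches per read equal the binomial mean beta*error_rate.

        Reads with and without errors are drawn from identical RNG states,
        so position-wise comparison isolates the substitutions.
        """
        seq = generate_background(SimulationConfig(N=5000), rng)
        cfg0 = SimulationConfig(N=5000, gamma=100.0, beta=200, error_rate=0.0)
        cfg1 = SimulationConfig(N=5000, gamma=100.0, beta=200, error_rate=0.01)
        clean = sample_reads(seq, cfg0, np.random.default_rng(12))
        noisy = sample_reads(seq, cfg1, np.random.default_rng(12))
        mm = [
            sum(a != b for a, b in zip(c, n))
            for c, n in zip(clean.reads, noisy.reads)
        ]
        mean = np.mean(mm)
        se = np.std(mm, ddof=1) / np.sqrt(len(mm))
        assert abs(mean - 2.0) < 3 * se

    def test_mean_depth_matches_coverage(self, rng):
        cfg = SimulationConfig(N=10_000, gamma=5.0, beta=200)
        seq = generate_background(cfg, rng)
        rs = sample_reads(seq, cfg, rng)
        assert abs(rs.n_reads * cfg.beta / cfg.N - 5.0) <= 0.25

    def test_both_strands_flips_about_half(self, rng):
        cfg = SimulationConfig(N=2000, gamma=20.0, beta=100, both_strands=True)
        seq = generate_background(cfg, rng)
        rs = sample_reads(seq, cfg, rng)
        fwd = sum(r in seq for r in rs.reads)
        assert 0.3 < fwd / rs.n_reads < 0.7


class TestExperiment:
    def test_default_sizes(self):
        cfg = SimulationConfig(N=500, lam=0.0, gamma=1.0, beta=100, seed=3)
        pos, neg = build_experiment(cfg, 20, 20)
        assert len(pos) == 20 and len(neg) == 20

    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(N=500, lam=0.01, model="FMM", gamma=2.0, beta=100, seed=9)
        a = build_experiment(cfg, 3, 3)
        b = build_experiment(cfg, 3, 3)
        assert [rs.reads for rs in a[0] + a[1]] == [rs.reads for rs in b[0] + b[1]]

    def test_different_seeds_differ(self):
        cfg1 = SimulationConfig(N=500, gamma=2.0, beta=100, seed=1)
        cfg2 = SimulationConfig(N=500, gamma=2.0, beta=100, seed=2)
        a = build_experiment(cfg1, 2, 2)
        b = build_experiment(cfg2, 2, 2)
        assert a[0][0].reads != b[0][0].reads


class TestGenomeFamily:
    def test_leaf_sequences_and_divergence(self, rng):
        from under2.io import read_newick

        tree = read_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2);")
        genomes = evolve_genomes(tree, 10_000, rng)
        assert set(genomes) == {"A", "B", "C", "D"}
        diff_ab = np.mean([a != b for a, b in zip(genomes["A"], genomes["B"])])
        diff_ac = np.mean([a != b for a, b in zip(genomes["A"], genomes["C"])])
        assert 0.10 < diff_ab < 0.20  # ~0.2 substitutions/site minus back-hits
        assert diff_ab < diff_ac
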