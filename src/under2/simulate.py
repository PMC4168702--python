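"""Benchmark input generation: backgrounds, motif implantation, sequencing.

Negative sequences are backgrounds with no shared signal: i.i.d. uniform,
i.i.d. GC-rich (p_A = p_T = 1/6, p_C = p_G = 1/3), or a window of a
user-supplied FASTA.  Positive sequences carry implanted motifs under one
of three correlation models, scanned left to right with per-position
intensity lambda:

* CM  -- one fixed length-5 motif;
* SMM -- five motifs (lengths 4, 5, 5, 6, 6), each or its reverse
         complement, all ten variants equally likely;
* FMM -- the same five motifs with the reverse also allowed (15 variants).

Sequencing draws M = ceil(gamma * N / beta) reads of fixed length beta at
uniform start positions, optionally flipping each read to the reverse
complement and substituting bases at a configurable error rate.  All
randomness flows from one integer seed through numpy SeedSequence
spawning, so every artefact is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import read_sequences
from .markov import MarkovModel, stationary_distribution
from .readset import ReadSet

__all__ = [
    "SimulationConfig",
    "DEFAULT_CM_MOTIF",
    "DEFAULT_MOTIFS",
    "generate_background",
    "implant_motifs",
    "sample_reads",
    "build_experiment",
    "evolve_genomes",
    "sample_markov_read_matrix",
    "count_word_occurrences",
    "stationary_markov_model",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

#: Motif strings are configuration, not ground truth: the correlation models
#: only fix their number and lengths, so these defaults are arbitrary
#: documented constants.
DEFAULT_CM_MOTIF = "ACGTC"
#: the first motif is the length-5 word the common-motif model implants
DEFAULT_MOTIFS = (DEFAULT_CM_MOTIF, "GATC", "TTGCA", "GATCGA", "CCATGG")

_GC_RICH = np.array([1 / 6, 1 / 3, 1 / 3, 1 / 6])


@dataclass
class SimulationConfig:
    """Parameters of one benchmark condition.

    ``lam`` is the per-position motif intensity; ``gamma`` the coverage;
    ``beta`` the (exact) read length; ``error_rate`` the per-base
    substitution probability of the sequencing stand-in.
    """

    N: int = 2000
    lam: float = 0.001
    model: str = "NONE"  # CM, SMM, FMM or NONE
    motifs: tuple = DEFAULT_MOTIFS
    background: str = "uniform"  # uniform, gcrich, fasta-window
    fasta_path: str | None = None
    gamma: float = 5.0
    beta: int = 200
    error_rate: float = 0.0
    both_strands: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")
        if self.gamma <= 0 or self.beta < 1 or self.N < self.beta:
            raise ValueError("require gamma > 0, beta >= 1 and N >= beta")
        if self.model not in ("CM", "SMM", "FMM", "NONE"):
            raise ValueError("model must be one of CM, SMM, FMM, NONE")
        if self.background not in ("uniform", "gcrich", "fasta-window"):
            raise ValueError("background must be uniform, gcrich or fasta-window")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for ch, c in _CODE.items():
        lut[ord(ch)] = c
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_background(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """One negative background sequence of length N."""
    if cfg.background == "uniform":
        return _decode(rng.integers(0, 4, cfg.N).astype(np.int8))
    if cfg.background == "gcrich":
        return _decode(rng.choice(4, size=cfg.N, p=_GC_RICH).astype(np.int8))
    if cfg.fasta_path is None:
        raise ValueError("fasta-window background requires fasta_path")
    records = [r for r in read_sequences(cfg.fasta_path) if len(r.seq) >= cfg.N]
    if not records:
        raise ValueError(f"no record in {cfg.fasta_path} is at least {cfg.N} bp long")
    rec = records[int(rng.integers(0, len(records)))]
    start = int(rng.integers(0, len(rec.seq) - cfg.N + 1))
    window = rec.seq[start : start + cfg.N]
    if "N" in window:
        window = window.replace("N", "A")  # backgrounds must be strict ACGT
    return window


def _motif_variants(cfg: SimulationConfig) -> list[str]:
    comp = str.maketrans("ACGT", "TGCA")
    if cfg.model == "CM":
        m = cfg.motifs[0]
        if len(m) != 5:
            raise ValueError("the CM motif must have length 5")
        return [m]
    motifs = list(cfg.motifs)
    if len(motifs) != 5:
        raise ValueError(f"{cfg.model} requires exactly five motifs")
    out = []
    for m in motifs:
        out.append(m)
        out.append(m[::-1].translate(comp))  # reverse complement
        if cfg.model == "FMM":
            out.append(m[::-1])  # plain reverse
    return out


def implant_motifs(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Overwrite motif copies into the sequence at per-position intensity lambda.

    The scan moves left to right; with probability lambda the next |m|
    symbols are overwritten with a uniformly chosen variant and the scan
    jumps past it (implanted motifs never overlap), otherwise it advances
    one position.  A variant longer than the remaining suffix is skipped.
    Output length equals input length.
    """
    if cfg.model == "NONE":
        raise ValueError("implant_motifs requires a correlation model")
    variants = [_encode(v) for v in _motif_variants(cfg)]
    codes = _encode(seq).copy()
    n = len(codes)
    coin = rng.random(n)
    j = 0
    while j < n:
        if coin[j] < cfg.lam:
            v = variants[int(rng.integers(0, len(variants)))]
            if j + len(v) <= n:
                codes[j : j + len(v)] = v
                j += len(v)
                continue
        j += 1
    return _decode(codes)


def sample_reads(seq: str, cfg: SimulationConfig, rng: np.random.Generator,
                 label: str = "sample") -> ReadSet:
    """M = ceil(gamma N / beta) reads of exact length beta at uniform starts."""
    codes = _encode(seq)
    n = len(codes)
    if n < cfg.beta:
        raise ValueError("sequence shorter than the read length")
    M = math.ceil(cfg.gamma * n / cfg.beta)
    starts = rng.integers(0, n - cfg.beta + 1, M)
    reads = codes[starts[:, None] + np.arange(cfg.beta)]
    if cfg.both_strands:
        flip = rng.random(M) < 0.5
        reads[flip] = 3 - reads[flip, ::-1]
    if cfg.error_rate > 0:
        err = rng.random(reads.shape) < cfg.error_rate
        shift = rng.integers(1, 4, reads.shape)
        reads[err] = (reads[err] + shift[err]) % 4
    return ReadSet(label, [_decode(row) for row in reads], beta=cfg.beta)


def build_experiment(
    cfg: SimulationConfig, n_pos: int = 20, n_neg: int = 20
) -> tuple[list[ReadSet], list[ReadSet]]:
    """Sequence n_pos motif-bearing and n_neg background sequences.

    Every sequence gets an independent background; positives additionally
    receive motif implants before sequencing.  Sub-seeds derive
    deterministically from ``cfg.seed``.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least two positive and two negative sequences")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_pos + n_neg)
    positives, negatives = [], []
    for i in range(n_pos):
        rng = np.random.default_rng(children[i])
        seq = generate_background(cfg, rng)
        if cfg.model != "NONE" and cfg.lam > 0:
            seq = implant_motifs(seq, cfg, rng)
        positives.append(sample_reads(seq, cfg, rng, label=f"pos{i}"))
    for i in range(n_neg):
        rng = np.random.default_rng(children[n_pos + i])
        seq = generate_background(cfg, rng)
        negatives.append(sample_reads(seq, cfg, rng, label=f"neg{i}"))
    return positives, negatives


def evolve_genomes(tree, N: int, rng: np.random.Generator) -> dict[str, str]:
    """Simulate a genome family along a tree with branch-length = expected
    substitutions per site (Jukes-Cantor-style site substitutions).

    ``tree`` is a dendropy tree whose edge lengths are substitution
    probabilities; returns {leaf label: sequence}.
    """
    root_seq = rng.integers(0, 4, N).astype(np.int8)
    out: dict[str, str] = {}
    stack = [(tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            rate = child.edge.length or 0.0
            mutated = seq.copy()
            mask = rng.random(N) < rate
            shift = rng.integers(1, 4, int(mask.sum()))
            mutated[mask] = (mutated[mask] + shift) % 4
            stack.append((child, mutated))
        if node.is_leaf():
            out[node.taxon.label] = _decode(seq)
    return out


def sample_markov_read_matrix(
    transition: np.ndarray, n_reads: int, beta: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_reads, beta) int8 matrix of reads from a stationary order-1 chain.

    Starting every read from the stationary distribution makes the marginal
    base law identical at every position, which is what the closed-form
    expectation p_w * M * (beta - |w| + 1) assumes.
    """
    transition = np.asarray(transition, dtype=float)
    pi = stationary_distribution(transition)
    cum = np.cumsum(transition, axis=1)
    out = np.empty((n_reads, beta), dtype=np.int8)
    out[:, 0] = rng.choice(4, size=n_reads, p=pi)
    for j in range(1, beta):
        u = rng.random(n_reads)
        out[:, j] = (u[:, None] > cum[out[:, j - 1]]).sum(axis=1)
    return out


def count_word_occurrences(reads: np.ndarray, word: str) -> np.ndarray:
    """Forward occurrence counts of ``word`` in each row of a read matrix."""
    w = _encode(word)
    k = len(w)
    beta = reads.shape[1]
    hits = np.zeros(reads.shape[0], dtype=np.int64)
    for j in range(beta - k + 1):
        hits += (reads[:, j : j + k] == w).all(axis=1)
    return hits


def stationary_markov_model(transition: np.ndarray, label: str = "generator") -> MarkovModel:
    """Order-1 model whose initial distribution is the chain's stationary law."""
    transition = np.asarray(transition, dtype=float)
    return MarkovModel(1, stationary_distribution(transition), transition, label)
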