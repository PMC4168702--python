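"""Readers and writers for the plain-text formats the toolkit exchanges.

FASTA/FASTQ parsing is delegated to Biopython.  The square PHYLIP distance
matrix dialect (classic 10-character name field) and Newick trees round-trip
through thin wrappers so every consumer sees the same two containers:
:class:`SequenceRecord` and :class:`DistanceMatrix`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "ParseError",
    "SequenceRecord",
    "DistanceMatrix",
    "read_sequences",
    "write_sequences",
    "read_phylip_matrix",
    "write_phylip_matrix",
    "read_newick",
    "write_newick",
]

_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed in the named format."""


@dataclass
class SequenceRecord:
    """A single named DNA sequence over {A, C, G, T, N}.

    The sequence is case-normalized to upper case; any other symbol is
    rejected at parse time.  ``N`` is accepted here and treated downstream
    as a position that matches no pattern.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _infer_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in (".fa", ".fasta", ".fna", ".ffn"):
        return "fasta"
    if suffix in (".fq", ".fastq"):
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path!r}; pass format=")


def read_sequences(path, format: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA or FASTQ file into a list of :class:`SequenceRecord`.

    Entry order is preserved.  FASTQ quality strings are parsed for
    validation but discarded (quality-aware processing is out of scope).
    """
    fmt = format or _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}; expected 'fasta' or 'fastq'")
    records: list[SequenceRecord] = []
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                records.append(SequenceRecord(rec.id, str(rec.seq)))
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ParseError(f"malformed {fmt} file {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no {fmt} records found in {path}")
    return records


def write_sequences(records, path, format: str = "fasta") -> None:
    """Write records as FASTA (or FASTQ with dummy maximal qualities)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n{rec.seq}\n")
            elif format == "fastq":
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")
            else:
                raise ValueError(f"unsupported format {format!r}")


@dataclass
class DistanceMatrix:
    """A labelled symmetric dissimilarity matrix with zero diagonal.

    Entries may be negative: the pattern-based dissimilarity is centred so
    that self-comparison is 0 and extremely similar inputs can dip below
    zero; tree reconstruction is invariant under the uniform shift used to
    restore non-negativity when a consumer requires it.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if n < 2:
            raise ValueError("a distance matrix needs at least two labels")
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric within 1e-9")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        # enforce exact symmetry / hollowness after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def write_phylip_matrix(m: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix (10-character name field)."""
    names = [lbl[:10] for lbl in m.labels]
    if len(set(names)) != len(names):
        raise ValueError(
            "labels collide after truncation to the 10-character PHYLIP name field"
        )
    with open(path, "w") as fh:
        fh.write(f"{len(m)}\n")
        for name, row in zip(names, m.values):
            fh.write(name.ljust(10) + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_matrix(path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix written by :func:`write_phylip_matrix`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"empty PHYLIP matrix file {path}")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ParseError(f"{path}: first line must hold the taxon count") from exc
    if len(lines) - 1 != n:
        raise ParseError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        labels.append(ln[:10].strip())
        try:
            row = [float(x) for x in ln[10:].split()]
        except ValueError as exc:
            raise ParseError(f"{path}: malformed matrix row {ln!r}") from exc
        if len(row) != n:
            raise ParseError(f"{path}: row for {labels[-1]!r} has {len(row)} values")
        rows.append(row)
    return DistanceMatrix(labels, np.array(rows))


def read_newick(path_or_string, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Read a Newick tree (file path or literal string) into a dendropy Tree."""
    kwargs = {"schema": "newick"}
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("(") or src.rstrip().endswith(";"):
            return dendropy.Tree.get(data=src, **kwargs)
        return dendropy.Tree.get(path=src, **kwargs)
    except Exception as exc:
        raise ParseError(f"cannot parse Newick input {path_or_string!r}: {exc}") from exc


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a dendropy tree as Newick."""
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
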