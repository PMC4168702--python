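"""Read sets, sequence transforms, and pattern occurrences.

A :class:`ReadSet` is the unit of comparison: a labelled collection of M
reads of nominal length beta over {A, C, G, T} (N tolerated; an N position
matches no pattern).  Patterns can occur in a read directly (F), in its
reverse (R), its base complement (C), or its reverse complement (RC); all
four transforms are searched by default to mimic strandedness and the
exchange of genetic material.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TRANSFORMS", "ReadSet", "Occurrence", "transforms_of", "occurrences"]

#: Canonical transform order used for document layout and priority coordinates.
TRANSFORMS = ("F", "R", "C", "RC")

_COMP = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


def _transform(read: str, transform: str) -> str:
    """Apply one of the four transforms; N passes through unchanged."""
    if transform == "F":
        return read
    if transform == "R":
        return read[::-1]
    if transform == "C":
        return read.translate(_COMP)
    if transform == "RC":
        return read[::-1].translate(_COMP)
    raise ValueError(f"unknown transform {transform!r}")


def transforms_of(read: str) -> dict[str, str]:
    """Return {F, R, C, RC} -> transformed string for a strict ACGT read."""
    read = read.upper()
    if not read:
        raise ValueError("cannot transform an empty read")
    if set(read) - {"A", "C", "G", "T"}:
        raise ValueError("transforms_of requires a read over ACGT only")
    return {t: _transform(read, t) for t in TRANSFORMS}


@dataclass
class ReadSet:
    """A labelled, ordered collection of reads.

    ``beta`` is the nominal read length; it defaults to the length of the
    first read.  ``total_length`` is the forward symbol count |R|, which for
    uniform-length reads equals M * beta.
    """

    label: str
    reads: list[str]
    beta: int | None = None

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError(f"read set {self.label!r} is empty")
        self.reads = [r.upper() for r in self.reads]
        for i, r in enumerate(self.reads):
            if not r:
                raise ValueError(f"read {i} of set {self.label!r} is empty")
            bad = set(r) - _ALPHABET
            if bad:
                raise ValueError(
                    f"read {i} of set {self.label!r} has invalid symbols {sorted(bad)}"
                )
        if self.beta is None:
            self.beta = len(self.reads[0])
        # memo for fitted background models (markov.fit_markov)
        self._fit_cache: dict = {}

    @classmethod
    def from_records(cls, label: str, records) -> "ReadSet":
        return cls(label, [rec.seq for rec in records])

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def total_length(self) -> int:
        """Forward symbol count |R| (transforms excluded)."""
        return sum(len(r) for r in self.reads)

    def possible_positions(self, word_length: int, transform_count: int = 1) -> int:
        """Number of start sites a word of the given length could occupy."""
        if word_length < 1:
            raise ValueError("word length must be >= 1")
        fwd = sum(max(0, len(r) - word_length + 1) for r in self.reads)
        return fwd * transform_count

    def transformed_reads(self, transform: str) -> list[str]:
        return [_transform(r, transform) for r in self.reads]


@dataclass(frozen=True, order=True)
class Occurrence:
    """A located match of a pattern: 0-based, half-open [offset, offset+length).

    ``offset`` is measured in the coordinate system of the transform string
    (not mapped back to forward coordinates).
    """

    set_id: int
    read_index: int
    transform: str
    offset: int
    length: int


def occurrences(
    word: str,
    rs: ReadSet,
    transforms=("F",),
    set_id: int = 1,
) -> list[Occurrence]:
    """All (possibly overlapping) matches of ``word`` in the requested transforms."""
    if not word:
        raise ValueError("cannot search for an empty word")
    word = word.upper()
    out: list[Occurrence] = []
    for t in transforms:
        if t not in TRANSFORMS:
            raise ValueError(f"unknown transform {t!r}")
        for idx, read in enumerate(rs.reads):
            hay = _transform(read, t)
            start = hay.find(word)
            while start != -1:
                out.append(Occurrence(set_id, idx, t, start, len(word)))
                start = hay.find(word, start + 1)
    return out
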