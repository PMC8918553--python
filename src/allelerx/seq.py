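"""Sequence primitives: records, alphabet normalization, reverse complement.

The internal alphabet is DNA — ``{A, C, G, T, N}``. RNA input is accepted
(``U`` is mapped to ``T`` on normalization) because Cas13 targets are RNA
but all sequence arithmetic here is done on the DNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Malformed sequence content (bad alphabet, empty sequence, ...)."""


def normalize_seq(seq: str) -> str:
    """Uppercase ``seq``, map U->T, and validate the {A,C,G,T,N} alphabet.

    Raises
    ------
    SequenceError
        If a character outside the alphabet remains; the message names the
        0-based position of the first offender.
    """
    norm = seq.upper().replace("U", "T")
    for i, base in enumerate(norm):
        if base not in ALPHABET:
            raise SequenceError(
                f"invalid character {base!r} at position {i} "
                f"(allowed: A, C, G, T, N)"
            )
    return norm


def revcomp(seq: str) -> str:
    """Reverse complement of a {A,C,G,T,N} string; N maps to N.

    Input is normalized first (lowercase and U accepted). An involution:
    ``revcomp(revcomp(s)) == s``.
    """
    return normalize_seq(seq).translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (FASTA/FASTQ payload).

    ``seq`` is normalized on construction: uppercased, U mapped to T, and
    restricted to {A,C,G,T,N}.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be nonempty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: sequence must be nonempty")
        self.seq = normalize_seq(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, revcomp(self.seq), self.description)


@dataclass
class FastqRead(SequenceRecord):
    """A sequencing read: a SequenceRecord plus its quality string.

    Qualities are carried through verbatim and never interpreted.
    """

    qual: str = field(default="")

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.qual) != len(self.seq):
            raise SequenceError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


def _mate_stem(read_id: str) -> str:
    stem = read_id.split()[0]
    if len(stem) > 2 and stem[-2] == "/" and stem[-1] in "12":
        stem = stem[:-2]
    return stem


@dataclass
class ReadPair:
    """Mated reads of one sequenced fragment.

    Mate ids must share a common stem (identical up to a ``/1``/``/2``
    suffix or a trailing whitespace-delimited tag).
    """

    r1: FastqRead
    r2: FastqRead

    def __post_init__(self) -> None:
        if _mate_stem(self.r1.id) != _mate_stem(self.r2.id):
            raise SequenceError(
                f"mate ids do not share a stem: {self.r1.id!r} vs {self.r2.id!r}"
            )
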