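"""Tiled spacer design across a point mutation.

For a Cas13-family effector with an L-nt spacer (30 nt for CasRx and
PspCas13b) and a single-nucleotide target variant, every spacer window that
covers the variant is a design candidate: the variant can sit at any of the
L positions of the window. This module enumerates all such windows on the
transcript, names them ``sg1..sgN`` in order of the variant's offset within
the window, and reports both the sense target window and the spacer (its
reverse complement, the sequence that base-pairs with the transcript).

CasRx has no protospacer flanking sequence (PFS) requirement, so no PFS
filter is applied by default; an optional flanking-base filter is exposed
for effectors that need one (e.g. PspCas13b), with a configurable rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

from allelerx.seq import SequenceRecord, revcomp


class DesignError(ValueError):
    """Inconsistent mutation/transcript input."""


@dataclass(frozen=True)
class PointMutation:
    """A single-base substitution at a 0-based transcript index."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise DesignError("ref_base and alt_base must differ")


@dataclass(frozen=True)
class GuideCandidate:
    """One tiled spacer window covering the mutation.

    ``target_window`` is the sense-strand window of the transcript;
    ``spacer`` is its reverse complement. ``mut_offset`` is the 0-based
    offset of the mutated base inside the window.
    """

    name: str
    window_start: int
    target_window: str
    mut_offset: int
    spacer: str


def validate_mutation(
    transcript_wt: SequenceRecord, transcript_mut: SequenceRecord
) -> PointMutation:
    """Locate the unique differing base between two equal-length transcripts.

    Raises :class:`DesignError` if the sequences differ at zero positions or
    at more than one (the message states the count and the first two
    differing positions).
    """
    if len(transcript_wt) != len(transcript_mut):
        raise DesignError(
            f"transcripts differ in length: {len(transcript_wt)} vs {len(transcript_mut)}"
        )
    diffs = [
        i
        for i, (a, b) in enumerate(zip(transcript_wt.seq, transcript_mut.seq))
        if a != b
    ]
    if len(diffs) != 1:
        shown = ", ".join(map(str, diffs[:2])) or "none"
        raise DesignError(
            f"expected exactly 1 differing position, found {len(diffs)} "
            f"(first positions: {shown})"
        )
    pos = diffs[0]
    return PointMutation(
        position=pos,
        ref_base=transcript_wt.seq[pos],
        alt_base=transcript_mut.seq[pos],
    )


def enumerate_tiled_guides(
    transcript: SequenceRecord,
    mutation: PointMutation,
    length: int = 30,
    allele: Literal["mut", "wt"] = "mut",
    pfs_filter: Callable[[str, str], bool] | None = None,
) -> list[GuideCandidate]:
    """Enumerate every length-``length`` window containing the mutation.

    One candidate per feasible offset ``o`` in ``[0, length)`` of the
    mutated base within the window (``window_start = position - o``),
    keeping only windows fully inside the transcript. Candidates are
    ordered by increasing ``mut_offset`` and named ``sg1..sgN``.

    Parameters
    ----------
    transcript
        The transcript the guides target. With ``allele="mut"`` (default)
        it must carry ``mutation.alt_base`` at ``mutation.position``; with
        ``allele="wt"``, ``mutation.ref_base``.
    pfs_filter
        Optional predicate ``f(upstream_base, downstream_base) -> bool``
        applied to the transcript bases flanking the window (empty string
        at transcript ends); windows failing it are dropped. Off by
        default: CasRx has no PFS restriction.
    """
    if length < 1:
        raise DesignError("spacer length must be >= 1")
    seq = transcript.seq
    pos = mutation.position
    if not 0 <= pos < len(seq):
        raise DesignError(
            f"mutation position {pos} outside transcript of length {len(seq)}"
        )
    expected = mutation.alt_base if allele == "mut" else mutation.ref_base
    if seq[pos] != expected:
        raise DesignError(
            f"transcript base at position {pos} is {seq[pos]!r}, "
            f"expected {expected!r} for the {allele.upper()} allele"
        )

    candidates: list[GuideCandidate] = []
    for offset in range(length):
        start = pos - offset
        if start < 0 or start + length > len(seq):
            continue
        window = seq[start : start + length]
        assert window[offset] == expected
        if pfs_filter is not None:
            up = seq[start - 1] if start > 0 else ""
            down = seq[start + length] if start + length < len(seq) else ""
            if not pfs_filter(up, down):
                continue
        candidates.append(
            GuideCandidate(
                name=f"sg{len(candidates) + 1}",
                window_start=start,
                target_window=window,
                mut_offset=offset,
                spacer=revcomp(window),
            )
        )
    return candidates
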