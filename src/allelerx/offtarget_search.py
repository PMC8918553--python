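"""Mismatch-tolerant off-target candidate search.

Enumerates every window of a sequence database within a Hamming-distance
budget of a spacer query, on one or both strands, and ranks hits by
mismatch count to produce a "top N most likely off-target sites" report.

The matching model is substitution-only: Cas13 spacer/target duplexes are
annotated by base mismatches and no indels are modeled. Ambiguous bases
(N) in the subject count as mismatches; the query itself must be
unambiguous.

Two search paths are provided. ``scan_bruteforce`` compares the query
against every window directly and serves as the reference oracle.
``find_offtargets`` uses pigeonhole k-mer seeding — for a budget of k
mismatches the query is cut into k+1 disjoint seeds of length
floor(L/(k+1)); any window within k mismatches must contain at least one
seed exactly, so exact seed lookups in a k-mer index followed by Hamming
verification are complete. Small databases fall back to the direct scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from allelerx.seq import SequenceRecord, normalize_seq, revcomp

Strands = Literal["both", "sense"]

# below this many database bases the direct scan is used; seeding pays off
# only for larger subjects
_SEED_MIN_DB = 20_000
_SEED_MIN_LEN = 3


class OffTargetError(ValueError):
    """Invalid off-target query or database."""


@dataclass(frozen=True)
class OffTargetHit:
    """One database window within the mismatch budget.

    ``start`` is the 0-based forward-strand coordinate of the half-open
    window on the subject. ``subject_window`` is oriented to the query:
    for '-' strand hits it is the reverse complement of the forward-strand
    window, so ``hamming(query, subject_window) == n_mismatch`` always
    holds, and ``mismatch_positions`` are 0-based offsets within the query.
    """

    subject_id: str
    start: int
    strand: str  # '+' or '-'
    n_mismatch: int
    mismatch_positions: tuple[int, ...]
    subject_window: str


def _validate(query: str, db: Sequence[SequenceRecord], max_mismatch: int) -> str:
    query = normalize_seq(query)
    if len(query) < 8:
        raise OffTargetError(f"query too short ({len(query)} nt, need >= 8)")
    if "N" in query:
        raise OffTargetError("ambiguous base N in query is not allowed")
    if not 0 <= max_mismatch < len(query):
        raise OffTargetError(
            f"max_mismatch must be in [0, {len(query) - 1}], got {max_mismatch}"
        )
    if not db:
        raise OffTargetError("empty database")
    return query


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _hit(
    subject: SequenceRecord, start: int, strand: str, query: str
) -> OffTargetHit:
    window = subject.seq[start : start + len(query)]
    oriented = window if strand == "+" else revcomp(window)
    positions = tuple(
        i for i, (q, s) in enumerate(zip(query, oriented)) if q != s
    )
    return OffTargetHit(
        subject_id=subject.id,
        start=start,
        strand=strand,
        n_mismatch=len(positions),
        mismatch_positions=positions,
        subject_window=oriented,
    )


def _scan_subject(
    query_arr: np.ndarray, subject_arr: np.ndarray, max_mismatch: int
) -> np.ndarray:
    """Forward-strand window starts within the budget (vectorized)."""
    if len(subject_arr) < len(query_arr):
        return np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(subject_arr, len(query_arr))
    mism = (windows != query_arr).sum(axis=1)
    return np.nonzero(mism <= max_mismatch)[0]


def scan_bruteforce(
    query: str,
    db: Sequence[SequenceRecord],
    max_mismatch: int,
    strands: Strands = "both",
) -> list[OffTargetHit]:
    """Direct position-by-position scan of every database window.

    The reference oracle for :func:`find_offtargets`; intended for small
    databases and tests, with no performance promise. Output is unranked
    (database order, then start, '+' before '-').
    """
    query = _validate(query, db, max_mismatch)
    q_fwd = _encode(query)
    q_rev = _encode(revcomp(query))
    hits: list[OffTargetHit] = []
    for subject in db:
        s_arr = _encode(subject.seq)
        per_start: dict[int, list[str]] = {}
        for start in _scan_subject(q_fwd, s_arr, max_mismatch):
            per_start.setdefault(int(start), []).append("+")
        if strands == "both":
            # a '-' hit means the query matches the reverse strand, i.e.
            # revcomp(query) occurs on the forward strand
            for start in _scan_subject(q_rev, s_arr, max_mismatch):
                per_start.setdefault(int(start), []).append("-")
        for start in sorted(per_start):
            for strand in per_start[start]:
                hits.append(_hit(subject, start, strand, query))
    return hits


def _seeded_starts(
    query: str, subject: SequenceRecord, index: dict[str, list[int]], k: int
) -> set[int]:
    """Candidate window starts on one subject via pigeonhole seeds."""
    L = len(query)
    seed_len = L // (k + 1)
    starts: set[int] = set()
    limit = len(subject.seq) - L
    for piece in range(k + 1):
        offset = piece * seed_len
        seed = query[offset : offset + seed_len]
        for pos in index.get(seed, ()):
            start = pos - offset
            if 0 <= start <= limit:
                starts.add(start)
    return starts


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def find_offtargets(
    query: str,
    db: Sequence[SequenceRecord],
    max_mismatch: int,
    top_n: int | None = 10,
    strands: Strands = "both",
    exclude: Iterable[tuple[str, int]] = (),
) -> list[OffTargetHit]:
    """Ranked off-target candidates of ``query`` across ``db``.

    All windows within ``max_mismatch`` Hamming distance on the requested
    strands, ranked ascending by mismatch count with deterministic
    tie-breaking (subject id, start, '+' before '-'), truncated to
    ``top_n`` (None keeps all). ``exclude`` drops (subject_id, start)
    sites, e.g. the on-target locus.

    Uses pigeonhole-seeded exact k-mer lookup with Hamming verification on
    large databases; falls back to the direct scan when the database is
    small or the seed length degenerates.
    """
    query = _validate(query, db, max_mismatch)
    total = sum(len(s) for s in db)
    seed_len = len(query) // (max_mismatch + 1)
    if total < _SEED_MIN_DB or seed_len < _SEED_MIN_LEN:
        hits = scan_bruteforce(query, db, max_mismatch, strands)
    else:
        queries = [("+", query)]
        if strands == "both":
            queries.append(("-", revcomp(query)))
        hits = []
        for subject in db:
            if len(subject.seq) < len(query):
                continue
            index = _kmer_index(subject.seq, seed_len)
            s_arr = _encode(subject.seq)
            for strand, oriented_query in queries:
                q_arr = _encode(oriented_query)
                for start in sorted(
                    _seeded_starts(oriented_query, subject, index, max_mismatch)
                ):
                    window = s_arr[start : start + len(query)]
                    if int((window != q_arr).sum()) <= max_mismatch:
                        hits.append(_hit(subject, start, strand, query))
    excluded = set(exclude)
    hits = [h for h in hits if (h.subject_id, h.start) not in excluded]
    hits.sort(
        key=lambda h: (h.n_mismatch, h.subject_id, h.start, 0 if h.strand == "+" else 1)
    )
    return hits if top_n is None else hits[:top_n]


def hit_key(hit: OffTargetHit) -> tuple[str, int, str, int]:
    """Identity tuple used to compare hit sets across search paths."""
    return (hit.subject_id, hit.start, hit.strand, hit.n_mismatch)
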