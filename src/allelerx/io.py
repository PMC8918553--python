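"""FASTA/FASTQ/TSV readers and writers.

FASTA/FASTQ parsing is delegated to Biopython; this module adds alphabet
normalization, gzip sniffing by file extension, paired-FASTQ streaming with
constant memory per record, and format errors that name the offending
record. All tables are TSV with a header row.
"""

from __future__ import annotations

import gzip
import logging
import sys
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from allelerx.seq import FastqRead, ReadPair, SequenceRecord

logger = logging.getLogger("allelerx")


class FormatError(ValueError):
    """Malformed input file."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read all records of a FASTA file.

    Multi-line sequences are concatenated; lowercase and U are normalized.
    An empty file or sequence data before the first header is a
    :class:`FormatError`.
    """
    with _open_text(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: sequence data before first '>' header")
    with _open_text(path) as handle:
        records = [
            SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
            for rec in SeqIO.parse(handle, "fasta")
        ]
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> Iterator[ReadPair]:
    """Stream mated FASTQ records from two synchronized files.

    Yields one :class:`ReadPair` per record pair, in file order, holding
    only the current pair in memory. A record-count mismatch between the
    two files raises :class:`FormatError` naming the 0-based record index.
    """
    with _open_text(path_r1) as h1, _open_text(path_r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = path_r1 if rec1 is None else path_r2
                raise FormatError(
                    f"record count mismatch at record index {index}: "
                    f"{short} is exhausted"
                )
            (t1, s1, q1), (t2, s2, q2) = rec1, rec2
            yield ReadPair(
                r1=FastqRead(id=t1, seq=s1, qual=q1),
                r2=FastqRead(id=t2, seq=s2, qual=q2),
            )
            index += 1


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path_r1: str | Path, path_r2: str | Path
) -> int:
    """Write mated reads to two FASTQ files; returns the pair count."""
    n = 0
    with _open_text(path_r1, "wt") as h1, _open_text(path_r2, "wt") as h2:
        for pair in pairs:
            h1.write(f"@{pair.r1.id}\n{pair.r1.seq}\n+\n{pair.r1.qual}\n")
            h2.write(f"@{pair.r2.id}\n{pair.r2.seq}\n+\n{pair.r2.qual}\n")
            n += 1
    return n


def setup_logging(level: str = "INFO", stage: str | None = None) -> None:
    """Stage-tagged logging to standard error."""
    tag = f"[{stage}] " if stage else ""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format=f"%(asctime)s {tag}%(levelname)s %(message)s",
        force=True,
    )
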