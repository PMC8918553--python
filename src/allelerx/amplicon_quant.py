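"""Amplicon deep-sequencing allele quantification.

Reads of a heterozygous amplicon are segregated into wild-type and mutant
transcripts by the presence of short allele *signatures* — two 30-mers
spanning the point mutation, differing at one base — searched in both
orientations. Each mate is classified independently; the fragment label is
the consensus of its mates, with conflicts treated conservatively as
ambiguous and excluded from allele fractions.

From the classified tallies the module computes the mutant allele fraction
(``actual proportion``), the mutant/wild-type read ratio, and the
knockdown efficiency

    efficiency = 100 x (theoretical - actual) / theoretical

where the theoretical proportion is the mutant share expected without
knockdown — 50% for a heterozygote expressing both alleles equally.

Default signatures are the Tmc1 Beethoven (c.1235T>A, p.M412K) pair; the
wild-type sense 30-mer is reconstructed as the reverse complement of its
antisense partner (see AlleleSignatureSet).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from allelerx.seq import ReadPair, hamming, normalize_seq, revcomp

logger = logging.getLogger("allelerx")

# Tmc1 Beethoven signature pair, sense orientation. The mutant 30-mer is as
# printed in the source assay; the wild-type 30-mer is the reverse
# complement of its printed antisense signature (the printed wild-type
# sense sequence is 28 nt and carries an apparent 2-nt omission).
MUT_SENSE_SIGNATURE = "ATGTCCCTCCTGGGGAAGTTCTGTCCCACC"
WT_SENSE_SIGNATURE = "ATGTCCCTCCTGGGGATGTTCTGTCCCACC"


class QuantError(ValueError):
    """Invalid quantification input."""


class Label(enum.Enum):
    WT = "WT"
    MUT = "MUT"
    AMBIGUOUS = "AMBIGUOUS"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class AlleleSignatureSet:
    """WT/mutant signature pair; antisense forms are always derived.

    ``max_mismatch`` > 0 enables Hamming-tolerant matching (the signature
    is slid along the read and matches any window within that distance).
    """

    wt_sense: str
    mut_sense: str
    max_mismatch: int = 0
    wt_anti: str = field(init=False)
    mut_anti: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt_sense", normalize_seq(self.wt_sense))
        object.__setattr__(self, "mut_sense", normalize_seq(self.mut_sense))
        if not self.wt_sense or not self.mut_sense:
            raise QuantError("signatures must be nonempty")
        if self.wt_sense == self.mut_sense:
            raise QuantError("wild-type and mutant signatures must differ")
        if self.max_mismatch < 0:
            raise QuantError("max_mismatch must be >= 0")
        object.__setattr__(self, "wt_anti", revcomp(self.wt_sense))
        object.__setattr__(self, "mut_anti", revcomp(self.mut_sense))


def default_signatures(max_mismatch: int = 0) -> AlleleSignatureSet:
    """The Tmc1 Beethoven WT/mutant 30-mer signature pair."""
    return AlleleSignatureSet(
        wt_sense=WT_SENSE_SIGNATURE,
        mut_sense=MUT_SENSE_SIGNATURE,
        max_mismatch=max_mismatch,
    )


@dataclass(frozen=True)
class AlleleCounts:
    """Fragment tallies; the four classes partition the total."""

    n_wt: int = 0
    n_mut: int = 0
    n_ambiguous: int = 0
    n_unclassified: int = 0

    @property
    def n_total(self) -> int:
        return self.n_wt + self.n_mut + self.n_ambiguous + self.n_unclassified

    @property
    def n_classified(self) -> int:
        return self.n_wt + self.n_mut


@dataclass(frozen=True)
class KnockdownResult:
    """Allele fractions over classified reads and the efficiency statistic."""

    actual_prop: float  # percent mutant among classified fragments
    theoretical_prop: float  # percent; 50 for a heterozygote
    efficiency: float  # percent
    allele_ratio: float  # n_mut / n_wt


def _contains_within(seq: str, pattern: str, k: int) -> bool:
    """Does seq contain a window within Hamming distance k of pattern?"""
    if k == 0:
        return pattern in seq
    n, m = len(seq), len(pattern)
    if n < m:
        return False
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    return bool(((windows != p).sum(axis=1) <= k).any())


def classify_read(seq: str, sig: AlleleSignatureSet) -> Label:
    """Assign one read to WT/MUT by signature presence in either orientation.

    A read matching signatures of both alleles (e.g. a chimera) is
    AMBIGUOUS; a read matching neither is UNCLASSIFIED.
    """
    if not seq:
        raise QuantError("empty read sequence")
    k = sig.max_mismatch
    has_wt = _contains_within(seq, sig.wt_sense, k) or _contains_within(
        seq, sig.wt_anti, k
    )
    has_mut = _contains_within(seq, sig.mut_sense, k) or _contains_within(
        seq, sig.mut_anti, k
    )
    if has_wt and has_mut:
        return Label.AMBIGUOUS
    if has_wt:
        return Label.WT
    if has_mut:
        return Label.MUT
    return Label.UNCLASSIFIED


def _reconcile(a: Label, b: Label) -> Label:
    if Label.AMBIGUOUS in (a, b):
        return Label.AMBIGUOUS
    if {a, b} == {Label.WT, Label.MUT}:
        return Label.AMBIGUOUS
    if a is Label.UNCLASSIFIED:
        return b
    return a


def count_alleles(pairs: Iterable[ReadPair], sig: AlleleSignatureSet) -> AlleleCounts:
    """Classify each fragment from its mates and tally.

    Each mate is classified independently; the fragment takes the mate
    label when the other mate is UNCLASSIFIED or agrees, and is AMBIGUOUS
    when the mates conflict (WT vs MUT) or either mate is itself ambiguous.
    """
    tally = {label: 0 for label in Label}
    n = 0
    for pair in pairs:
        fragment = _reconcile(
            classify_read(pair.r1.seq, sig), classify_read(pair.r2.seq, sig)
        )
        tally[fragment] += 1
        n += 1
    if n == 0:
        logger.warning("count_alleles: empty read stream, all tallies zero")
    return AlleleCounts(
        n_wt=tally[Label.WT],
        n_mut=tally[Label.MUT],
        n_ambiguous=tally[Label.AMBIGUOUS],
        n_unclassified=tally[Label.UNCLASSIFIED],
    )


def knockdown_efficiency(actual_prop: float, theoretical_prop: float = 50.0) -> float:
    """100 x (theoretical - actual) / theoretical, both in percent."""
    if theoretical_prop == 0:
        raise QuantError("theoretical proportion must be > 0")
    if not 0 <= actual_prop <= 100:
        raise QuantError(f"actual proportion {actual_prop} outside [0, 100]")
    return 100.0 * (theoretical_prop - actual_prop) / theoretical_prop


def allele_ratio(counts: AlleleCounts, sample: str = "sample") -> float:
    """Mutant/wild-type fragment ratio over classified fragments."""
    if counts.n_wt == 0:
        raise QuantError(f"{sample}: no wild-type reads, allele ratio undefined")
    return counts.n_mut / counts.n_wt


def mutant_fraction(counts: AlleleCounts) -> float:
    """Mutant share of classified fragments, in [0, 1]."""
    if counts.n_classified == 0:
        raise QuantError("no classified reads, mutant fraction undefined")
    return counts.n_mut / counts.n_classified


def quantify(counts: AlleleCounts, theoretical_prop: float = 50.0) -> KnockdownResult:
    """Actual mutant proportion, allele ratio, and knockdown efficiency.

    Fractions are computed over classified fragments only; ambiguous and
    unclassified fragments are tallied but excluded.
    """
    actual = 100.0 * mutant_fraction(counts)
    return KnockdownResult(
        actual_prop=actual,
        theoretical_prop=theoretical_prop,
        efficiency=knockdown_efficiency(actual, theoretical_prop),
        allele_ratio=allele_ratio(counts),
    )


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float | None  # sample SD (n-1); None when n == 1
    n: int


def summarize_group(values: list[float]) -> GroupSummary:
    """Mean and sample SD across replicate samples (e.g. animals)."""
    if not values:
        raise QuantError("cannot summarize an empty group")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return GroupSummary(mean=float(arr.mean()), sd=sd, n=len(arr))


def signature_mutation_offset(sig: AlleleSignatureSet) -> int:
    """Offset of the single differing base between the sense signatures.

    Errors if the signatures differ at more than one position or in length.
    """
    if len(sig.wt_sense) != len(sig.mut_sense):
        raise QuantError("signatures differ in length")
    if hamming(sig.wt_sense, sig.mut_sense) != 1:
        raise QuantError("signatures must differ at exactly one base")
    return next(
        i for i, (a, b) in enumerate(zip(sig.wt_sense, sig.mut_sense)) if a != b
    )
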