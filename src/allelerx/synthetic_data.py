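"""Seeded simulators for every input the pipeline consumes.

Each generator takes an explicit integer seed, is byte-deterministic for a
given seed, and returns a :class:`SimTruth` record alongside its dataset.
The truth record carries the exact parameters used (mutant fraction, error
rate, planted site coordinates, true ratios, ...) so parameter-recovery
tests read truth rather than re-deriving it.

What is emulated
----------------
* **Amplicon reads** — a heterozygous two-allele amplicon mixture: each
  fragment is wild-type or mutant (alleles differ at one base inside the
  allele signatures), sequenced as a 150-bp paired-end fragment in either
  orientation, with independent per-base substitution errors. Qualities
  are uniform; no indels, PCR duplicates, or quality decay are modeled.
* **Transcriptome with planted sites** — uniform-random background
  sequences carrying copies of a spacer query mutated at exactly k
  positions, on either strand, with a rejection guarantee that the
  background holds no accidental near-match.
* **Screen wells** — reporter fluorescence intensities centered at
  ``nt_intensity x true_ratio`` with multiplicative Gaussian noise
  truncated at zero, three replicates by default.
* **Ct tables** — target Ct shifted by -log2(true relative expression)
  against a constant-mean reference gene, with additive Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from allelerx.amplicon_quant import AlleleSignatureSet, default_signatures
from allelerx.offtarget_search import scan_bruteforce, hit_key
from allelerx.seq import FastqRead, ReadPair, SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

AMPLICON_LEN = 250


class SimulationError(ValueError):
    """Invalid simulator parameters."""


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated dataset."""

    generator: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"generator": self.generator, "seed": self.seed, "params": self.params}

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2, default=str)
            handle.write("\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def default_amplicon_templates(
    sig: AlleleSignatureSet | None = None,
    amplicon_len: int = AMPLICON_LEN,
) -> tuple[SequenceRecord, SequenceRecord]:
    """Synthetic WT/mutant amplicon templates sharing fixed flanks.

    The allele signatures are centered in an ``amplicon_len``-nt amplicon
    whose flanking context is fixed random sequence (seeded constant, and
    rejected if it ever recreates a signature). This synthetic geometry
    stands in for the real assay amplicon, whose primer coordinates are
    not published; only the signature placement matters downstream.
    """
    sig = sig or default_signatures()
    sig_len = len(sig.wt_sense)
    if amplicon_len < sig_len:
        raise SimulationError("amplicon shorter than the allele signature")
    rng = np.random.default_rng(190707)  # fixed: templates are constants
    left_len = (amplicon_len - sig_len) // 2
    right_len = amplicon_len - sig_len - left_len
    for _ in range(100):
        left = _random_seq(rng, left_len)
        right = _random_seq(rng, right_len)
        wt = left + sig.wt_sense + right
        mut = left + sig.mut_sense + right
        clean = (
            wt.count(sig.wt_sense) == 1
            and mut.count(sig.mut_sense) == 1
            and sig.wt_anti not in wt
            and sig.mut_anti not in mut
            and sig.mut_sense not in wt
            and sig.mut_anti not in wt
            and sig.wt_sense not in mut
            and sig.wt_anti not in mut
        )
        if clean:
            return (
                SequenceRecord("wt_amplicon", wt, "synthetic WT amplicon"),
                SequenceRecord("mut_amplicon", mut, "synthetic mutant amplicon"),
            )
    raise SimulationError("could not draw signature-free flanks")


def simulate_amplicon_reads(
    wt_template: SequenceRecord,
    mut_template: SequenceRecord,
    n_fragments: int,
    mut_fraction: float,
    error_rate: float = 0.0,
    read_len: int = 150,
    anti_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[ReadPair], SimTruth]:
    """Paired-end reads from a two-allele amplicon mixture.

    Each fragment is mutant with probability ``mut_fraction``; with
    probability ``anti_fraction`` its orientation is flipped before
    sequencing. R1 reads the fragment 5' end, R2 the reverse complement of
    its 3' end. Substitution errors are independent per base at
    ``error_rate``; qualities are uniform 'I'.
    """
    if not 0 <= mut_fraction <= 1:
        raise SimulationError(f"mut_fraction {mut_fraction} outside [0, 1]")
    if not 0 <= error_rate <= 0.05:
        raise SimulationError(f"error_rate {error_rate} outside [0, 0.05]")
    if read_len > min(len(wt_template), len(mut_template)):
        raise SimulationError(
            f"read_len {read_len} exceeds template length "
            f"{min(len(wt_template), len(mut_template))}"
        )
    rng = np.random.default_rng(seed)
    n = n_fragments
    is_mut = rng.random(n) < mut_fraction
    flipped = rng.random(n) < anti_fraction

    # per (allele, orientation) the mates are fixed strings; index by
    # category then add errors
    def mates(template: str) -> tuple[np.ndarray, np.ndarray]:
        r1 = np.frombuffer(template[:read_len].encode(), dtype=np.uint8)
        r2 = np.frombuffer(revcomp(template[-read_len:]).encode(), dtype=np.uint8)
        return r1, r2

    combos = []
    for allele_seq in (wt_template.seq, mut_template.seq):
        for frag in (allele_seq, revcomp(allele_seq)):
            combos.append(mates(frag))
    cat = is_mut.astype(np.intp) * 2 + flipped.astype(np.intp)
    r1_bank = np.stack([c[0] for c in combos])
    r2_bank = np.stack([c[1] for c in combos])
    r1 = r1_bank[cat].copy()
    r2 = r2_bank[cat].copy()

    for mat in (r1, r2):
        if error_rate > 0:
            n_err = rng.binomial(read_len, error_rate, size=n)
            for i in np.nonzero(n_err)[0]:
                pos = rng.choice(read_len, size=n_err[i], replace=False)
                shift = rng.integers(1, 4, size=n_err[i])
                idx = _BASE_INDEX[mat[i, pos]]
                mat[i, pos] = _BASES[(idx + shift) % 4]

    qual = "I" * read_len
    pairs = [
        ReadPair(
            r1=FastqRead(id=f"frag{i:07d}/1", seq=bytes(r1[i]).decode(), qual=qual),
            r2=FastqRead(id=f"frag{i:07d}/2", seq=bytes(r2[i]).decode(), qual=qual),
        )
        for i in range(n)
    ]
    truth = SimTruth(
        generator="simulate_amplicon_reads",
        seed=seed,
        params={
            "n_fragments": n,
            "mut_fraction": mut_fraction,
            "error_rate": error_rate,
            "read_len": read_len,
            "anti_fraction": anti_fraction,
            "n_mut_true": int(is_mut.sum()),
            "n_flipped_true": int(flipped.sum()),
            "wt_template_id": wt_template.id,
            "mut_template_id": mut_template.id,
            "synthetic_amplicon_geometry": True,
        },
    )
    return pairs, truth


def simulate_transcriptome_with_sites(
    query: str,
    n_background: int,
    background_len: int,
    planted: Sequence[tuple[int, str]],
    seed: int = 0,
    guard_mismatch: int | None = None,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Random transcriptome carrying planted near-matches of ``query``.

    Each planted ``(n_mismatch, strand)`` site is the query with exactly
    that many distinct random substitutions, inserted at a recorded
    coordinate on the recorded strand. The background is guaranteed (by
    rejection against the brute-force scanner) to contain no other window
    within ``guard_mismatch`` of the query (default: the largest planted
    distance, or 3 when nothing is planted).
    """
    L = len(query)
    if any(d >= L for d, _ in planted):
        raise SimulationError("planted mismatch count must be < query length")
    if any(strand not in "+-" for _, strand in planted):
        raise SimulationError("planted strand must be '+' or '-'")
    if background_len < L:
        raise SimulationError(
            f"background_len {background_len} too short to host a {L}-nt site"
        )
    if n_background < 1:
        raise SimulationError("need at least one background sequence")
    guard = guard_mismatch
    if guard is None:
        guard = max((d for d, _ in planted), default=3)

    root = np.random.default_rng(seed)
    for _attempt in range(50):
        rng = np.random.default_rng(root.integers(0, 2**31))
        db = [
            SequenceRecord(f"tx{i + 1}", _random_seq(rng, background_len))
            for i in range(n_background)
        ]
        truth_sites: list[dict[str, Any]] = []
        occupied: dict[int, list[tuple[int, int]]] = {}
        ok = True
        for n_mismatch, strand in planted:
            site = _mutated_copy(query, n_mismatch, rng)
            inserted = site if strand == "+" else revcomp(site)
            placed = False
            for _ in range(200):
                subj = int(rng.integers(0, n_background))
                start = int(rng.integers(0, background_len - L + 1))
                if all(
                    start + L <= s or start >= e
                    for s, e in occupied.get(subj, [])
                ):
                    placed = True
                    break
            if not placed:
                ok = False
                break
            occupied.setdefault(subj, []).append((start, start + L))
            rec = db[subj]
            db[subj] = SequenceRecord(
                rec.id, rec.seq[:start] + inserted + rec.seq[start + L :]
            )
            truth_sites.append(
                {
                    "subject_id": rec.id,
                    "start": start,
                    "strand": strand,
                    "n_mismatch": n_mismatch,
                }
            )
        if not ok:
            continue
        # rejection guarantee: the scan at the guard distance finds the
        # planted sites and nothing else
        found = {
            hit_key(h)
            for h in scan_bruteforce(query, db, guard, strands="both")
        }
        expected = {
            (s["subject_id"], s["start"], s["strand"], s["n_mismatch"])
            for s in truth_sites
            if s["n_mismatch"] <= guard
        }
        if found == expected:
            truth = SimTruth(
                generator="simulate_transcriptome_with_sites",
                seed=seed,
                params={
                    "query": query,
                    "n_background": n_background,
                    "background_len": background_len,
                    "guard_mismatch": guard,
                    "planted_sites": truth_sites,
                },
            )
            return db, truth
    raise SimulationError("could not build a clean background in 50 attempts")


def _mutated_copy(query: str, n_mismatch: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(query.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(query), size=n_mismatch, replace=False)
    shift = rng.integers(1, 4, size=n_mismatch)
    arr[pos] = _BASES[(_BASE_INDEX[arr[pos]] + shift) % 4]
    return bytes(arr).decode("ascii")


def simulate_screen(
    true_ratios: Mapping[str, tuple[float, float]],
    nt_intensity: float = 10_000.0,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Well-intensity table for a reporter knockdown screen.

    ``true_ratios`` maps each guide to its true (ratio_mut, ratio_wt)
    versus the non-targeting control. NT wells center at ``nt_intensity``
    and guide wells at ``nt_intensity x true_ratio`` per reporter, with
    multiplicative Gaussian noise of coefficient of variation ``cv``
    truncated at zero. Three replicates per well by default.
    """
    if cv < 0:
        raise SimulationError("cv must be >= 0")
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for guide in ["NT", *sorted(true_ratios)]:
        for reporter, which in (("MUT", 0), ("WT", 1)):
            center = nt_intensity * (
                1.0 if guide == "NT" else true_ratios[guide][which]
            )
            noise = np.maximum(0.0, 1.0 + cv * rng.standard_normal(n_replicates))
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "guide_id": guide,
                        "reporter": reporter,
                        "replicate": rep,
                        "intensity": center * noise[rep - 1],
                    }
                )
    wells = pd.DataFrame(rows)
    truth = SimTruth(
        generator="simulate_screen",
        seed=seed,
        params={
            "true_ratios": {g: list(r) for g, r in true_ratios.items()},
            "true_specificity": {
                g: (r[0] / r[1] if r[1] else float("inf"))
                for g, r in true_ratios.items()
            },
            "nt_intensity": nt_intensity,
            "cv": cv,
            "n_replicates": n_replicates,
        },
    )
    return wells, truth


def simulate_ct_table(
    true_rel_expr: Mapping[str, float],
    conditions: Mapping[str, str],
    base_ct: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Ct table with known relative expression per sample.

    Target Ct is ``base_ct - log2(true_rel_expr)`` plus additive Gaussian
    noise; the reference gene sits at ``base_ct`` with independent noise.
    Control samples must carry true relative expression 1.
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    if set(true_rel_expr) != set(conditions):
        raise SimulationError("true_rel_expr and conditions must share sample ids")
    for sample, rel in true_rel_expr.items():
        if rel <= 0:
            raise SimulationError(f"true relative expression must be > 0 ({sample})")
        if conditions[sample] == "control" and rel != 1.0:
            raise SimulationError(
                f"control sample {sample!r} must have true relative expression 1"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for sample in sorted(true_rel_expr):
        rel = true_rel_expr[sample]
        rows.append(
            {
                "sample": sample,
                "condition": conditions[sample],
                "ct_target": base_ct
                - np.log2(rel)
                + noise_sd * rng.standard_normal(),
                "ct_reference": base_ct + noise_sd * rng.standard_normal(),
            }
        )
    ct = pd.DataFrame(rows)
    truth = SimTruth(
        generator="simulate_ct_table",
        seed=seed,
        params={
            "true_rel_expr": dict(true_rel_expr),
            "conditions": dict(conditions),
            "base_ct": base_ct,
            "noise_sd": noise_sd,
        },
    )
    return ct, truth
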