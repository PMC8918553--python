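# Methods

This note documents the models, statistics, numerical choices and
limitations behind `allelerx`. The setting is allele-specific RNA
knockdown: a CasRx (Cas13d) guide directed at a transcript that differs
from its wild-type counterpart at a single base (the *Tmc1* Beethoven
c.1235T>A substitution is the motivating case), with readouts from a
fluorescence reporter screen, targeted amplicon deep sequencing, candidate
off-target expression comparison, and RT-qPCR.

## Conventions

All coordinates are 0-based, half-open. Sequences are normalized on input:
uppercased, `U` mapped to `T` (targets are RNA; all sequence arithmetic is
done on the DNA alphabet `{A,C,G,T,N}`). Reverse complement maps `N` to
`N`. Gzip-compressed FASTA/FASTQ are accepted by extension.

## Guide tiling design

For spacer length `L` (default 30, the CasRx/PspCas13b spacer length) and
a point mutation at transcript index `p`, the candidate windows are the
substrings `[p-o, p-o+L)` for offsets `o = 0..L-1` that fit inside the
transcript — the mutation occupies every possible spacer position once.
Candidates are ordered by the mutation's offset within the window and
named `sg1..sgN`; with at least `L-1` nt of flank on each side there are
exactly `L` candidates. The emitted `spacer` is the reverse complement of
the sense target window (a crRNA spacer base-pairs with the transcript);
the sense window is reported too so either convention can be consumed.
Guides are designed against the mutant transcript by default (`allele=
"wt"` designs against wild type). No PFS filter is applied by default
because CasRx has no PFS requirement; a configurable flanking-base
predicate is available for effectors that need one. Thermodynamic or
accessibility scoring is out of scope.

## Screen scoring

Input is a well table of region-averaged fluorescence intensities
(`guide_id, reporter ∈ {MUT, WT}, replicate, intensity`), with `NT` as the
non-targeting control. The default aggregation is the ratio of averaged
intensities, `mean(guide wells) / mean(NT wells)` per reporter; the
specificity score is `ratio_MUT / ratio_WT`, and percent knockdown is
`100 × (1 − ratio)`. A second mode averages per-replicate ratios
`guide_i / NT_i`; the two differ when the instrument drifts between
replicates. Published screens of this design report a top-guide
specificity (0.089113 in the motivating study) that cannot be recovered
from the printed per-allele marginals (0.092 / 0.557 ≈ 0.165), so the
exact upstream aggregation is evidently different from either plain mode;
both modes are provided and neither claims to reproduce that constant.
Ranking is ascending specificity with deterministic tie-breaks (ratio_MUT,
then guide id). All ratio statistics are invariant to rescaling every
intensity by a common positive factor. The per-replicate SD of
`guide_i / mean(NT)` is reported beside each mean. Image processing
upstream of the intensity table, and ANOVA across guides, are out of
scope.

## Amplicon allele quantification

Reads are segregated by two 30-mer allele signatures spanning the
mutation (mutant `ATGTCCCTCCTGGGGAAGTTCTGTCCCACC`, wild-type
`ATGTCCCTCCTGGGGATGTTCTGTCCCACC`), each searched in sense and antisense
orientation. The antisense forms are always derived by reverse complement,
never supplied independently. The default wild-type sense 30-mer is
reconstructed from its antisense partner because the assay's printed
wild-type sense sequence is 28 nt and inconsistent with its own reverse
complement; any signature pair can be supplied via `--signatures`.

Matching is exact substring by default. A Hamming-tolerant mode
(`max_mismatch > 0`, sliding-window distance) is provided for
error-containing reads; note that at `max_mismatch ≥ 1` a read containing
one allele's signature exactly is also within distance 1 of the other
allele's signature and becomes AMBIGUOUS — the tolerant mode is therefore
only meaningful with signatures differing at more than `max_mismatch`
positions, and the default pipeline keeps `max_mismatch = 0`.

Each mate is classified independently into WT / MUT / AMBIGUOUS /
UNCLASSIFIED; the fragment label is the mate label when the other mate is
UNCLASSIFIED or agrees, and AMBIGUOUS when mates conflict or either mate
matches both alleles. This conservative reconciliation is a design choice
(the upstream description does not state one). The four tallies always
partition the fragments. No read-quality filtering is applied before
segregation, and no alignment, indel handling or UMI logic is performed.

Allele fractions and the mutant/wild-type ratio are computed over
classified fragments only (`n_wt + n_mut`); ambiguous and unclassified
fragments are reported but excluded. Knockdown efficiency is
`100 × (theoretical − actual) / theoretical` with both proportions in
percent; `theoretical` defaults to 50, the expectation for a heterozygote
expressing both alleles equally (an actual proportion of 14.88% then gives
70.24%). Group summaries (mean, sample SD with `n−1`, n) average
per-sample statistics, never pooled read counts.

## Off-target search

The query (a 30-nt spacer) is compared against every length-`L` window of
a sequence database under the Hamming metric — substitutions only, no
gaps, matching how Cas13 off-target candidates are annotated by base
mismatches. `N` in the subject counts as a mismatch; `N` in the query is
rejected. Both strands are searched by default (genome databases);
sense-only mode suits transcriptome databases since Cas13 targets RNA.

Two paths give identical results. The brute-force scan compares every
window (vectorized over windows) and serves as the test oracle. The main
path uses pigeonhole seeding: for a budget of `k` mismatches the query is
cut into `k+1` disjoint seeds of length `floor(L/(k+1))`; any qualifying
window must contain at least one seed exactly, so candidates are found by
exact seed lookup in a per-subject k-mer index and verified by direct
Hamming comparison. The seeded path engages when the database exceeds
20 kb and the seed length is at least 3; otherwise the scan is used (at
small sizes indexing costs more than scanning). Hits are ranked ascending
by mismatch count with deterministic tie-breaks (subject id, start, `+`
before `-`) and truncated to `top_n` (default 10, the conventional
candidate-list size); an exclusion list removes the on-target site. The
default budget is 10 mismatches for a 30-nt query — candidate lists in
this assay family carry many-mismatch sites, and no published cutoff
exists, so the budget is deliberately generous and configurable. The
ranking does not claim to reproduce any particular published top-10 list,
whose aligner and scoring are unstated.

## Expression statistics

**Candidate-gene comparison.** Each off-target candidate gene's FPKM
values are compared between two sample groups with a two-sided Welch
(unequal-variance) t-test — the "multiple unpaired t-tests" convention —
computed by `scipy.stats.ttest_ind(equal_var=False)` with the
Satterthwaite df recomputed in closed form. Genes with zero FPKM in every
sample of both groups are flagged undetected and not tested; genes with
zero variance in both groups and equal means are skipped as degenerate.
Raw p-values drive the significance call at α = 0.05 (matching the
plain per-gene convention); Benjamini–Hochberg adjusted p-values over the
tested genes are reported alongside, since small candidate panels are
still a multiple-testing family. Whole-transcriptome differential
expression is out of scope.

**ddCt.** Per sample, `dCt = Ct_target − Ct_reference`; `ddCt = dCt −
mean(dCt over control samples)`; relative expression `2^(−ddCt)`.
Amplification efficiency is fixed at 2 (perfect doubling) — the plain
ddCt algorithm, no standard-curve correction. The control group's
geometric mean relative expression is exactly 1 by construction; the
arithmetic mean exceeds 1 under noise (lognormal), so group summaries
report both. The statistic is invariant to adding a constant to a
sample's target and reference Ct simultaneously.

## Synthetic data

Every generator takes an explicit integer seed, is byte-deterministic
given the seed, and emits a truth record sufficient to recompute the
expected statistics analytically.

* **Amplicon reads** emulate a heterozygous two-allele mixture: each
  fragment is mutant with probability `mut_fraction`; orientation is
  flipped with probability 0.5; R1 reads the fragment 5' end and R2 the
  reverse complement of the 3' end (150 bp each); substitution errors are
  independent per base. Under exact matching, the expected unclassified
  mate fraction at error rate `e` is `1 − (1−e)^30` less the small term
  `(e/3)(1−e)^29` for the single error that converts one allele's
  signature into the other's. The default templates are 250-nt synthetic
  amplicons with the signatures centered in fixed random flanks (checked
  to contain no spurious signature copy): the real assay's amplicon
  length and primer positions are not published, so this geometry is a
  stand-in, marked `synthetic_amplicon_geometry` in truth records. Not
  modeled: indels, quality decay (uniform Q40), PCR duplicates, chimeras.
  Passing recovery tests therefore shows correctness of the classifier
  and estimator under substitution noise, not robustness to alignment
  artifacts in real libraries.
* **Transcriptomes with planted sites** insert copies of the query
  mutated at exactly `k` distinct random positions, on either strand, at
  recorded non-overlapping coordinates, into uniform-random background.
  The generator re-draws until a brute-force scan confirms the background
  contains no window within the guard distance (the largest planted
  distance; 3 when nothing is planted) other than the planted sites — for
  a 30-nt query and small guard this rejection virtually never triggers.
* **Screen wells** center guide wells at `nt_intensity × true_ratio` per
  reporter with multiplicative Gaussian noise truncated at zero
  (intensities cannot be negative), three replicates by default to mirror
  the standard triplicate design.
* **Ct tables** encode a sample's true relative expression as
  `−log2(rel)` cycles on the target against a constant-mean reference,
  with additive Gaussian noise (the standard log-scale qPCR noise model).

## Problem sizes and numerical choices

Simulation-based tests use 2,000–50,000 fragments per run and ten seeds
for the efficiency-recovery study — large enough that binomial
Monte-Carlo error (3 SE bands) is a few tenths of a percentage point,
small enough to keep the full suite under a minute. Recovery assertions
use analytic standard errors (binomial for fractions, delta method for
ratios, lognormal propagation for ddCt) at 3 SE. Welch/ddCt closed-form
agreement is asserted at 1e-10 absolute. Ties in every ranking are broken
deterministically so repeated runs are byte-stable.

## Known limitations

* Substitution-only matching everywhere: an indel in an amplicon read or
  near an off-target site is invisible to the Hamming model.
* The screen's exact published aggregation constant is not reproducible
  from its printed marginals (see above); results are defined by this
  package's two documented modes.
* Classification at `max_mismatch = 0` discards any read whose signature
  window carries a sequencing error (≈ 26% of mates at e = 1%); because
  the loss is allele-symmetric apart from the single discriminating base,
  the mutant-fraction estimator stays unbiased to first order, which the
  recovery tests confirm empirically.
* The off-target ranking is by mismatch count only; no expression
  weighting, RNA accessibility, or secondary-structure term.
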