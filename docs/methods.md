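# Methods

## The linear GC-bias model

A sequencing library is modelled as repeated draws of genomic
fragments. A candidate fragment F — uniform random start, insert
length a rounded Normal draw — is retained with probability

    P(F) = C · max(0, 1 + s · (GC(F) − GC_m)),

GC(F) being the fragment's GC fraction over unambiguous bases, GC_m
the mean GC fraction of all fragments of the nominal insert length
anchored at every genome position, s the degree of GC bias, and C a
normalization constant. GC is in fraction units (0–1), which is the
scale on which slopes of magnitude up to ~9 map onto normalized
coverage between 0 and ~2× the mean, matching what windowed coverage
scatter plots of real bacterial libraries show. The clamp at zero is
essential to the science: for |s| ≳ 1/(max |GC − GC_m|) the acceptance
probability reaches exactly zero in the GC tail, so those regions
receive no reads at any sequencing depth — the mechanism behind
persistent zero-coverage regions and missing assembly.

C is chosen as the reciprocal of the maximal weight over the genome's
own fragment-GC range, making P a valid probability in (0, 1]. C
cancels in every coverage-normalized quantity, so its choice affects
runtime (acceptance rate) but no estimate.

The model is deliberately linear. Unimodal ("both tails
under-covered") bias profiles exist in some libraries, but a linear
fit captures most published bacterial data sets, and a unimodal
profile can be viewed piecewise as two linear regimes.

## Simulation procedure

1. Compute GC_m and C from the genome at the nominal insert length.
2. Propose a fragment: uniform start, length ~ round(Normal(mean, sd)).
   Proposals shorter than 30 bp (vanishingly rare at the 180 ± 10
   default), running past the sequence end (linear mode), or containing
   any non-ACGT base are resampled.
3. Accept with probability P(F), optionally multiplied by a
   background-fluctuation tile multiplier (below), clamped to [0, 1].
4. Repeat until total read bases reach `target_coverage × genome length`
   (the standard fold-coverage stopping rule; the overshoot is less
   than one pair's worth of bases).
5. Cut reads of fixed length from the two fragment ends — FR
   orientation for paired-end, RF for mate-pair; fragments shorter than
   the read length yield truncated reads.
6. Apply per-cycle substitution errors: at cycle i the base is replaced
   by a uniformly chosen different base with probability rate[i].
   Quality strings encode the profile's rates as Phred = −10·log10(rate),
   capped at Q41, Sanger +33. Error profiles can be learned from real
   FASTQ as the per-cycle mean of 10^(−Q/10).

Defaults mirror the study conditions the package is built to explore:
100-bp reads, Normal(180, 10) inserts, 50X coverage, slopes spanning
−3.8 … +3.8; mate-pair libraries use Normal(3500, 500) inserts, RF
orientation, slope 0, 1X. All randomness flows from a single seed
through spawned per-purpose streams, so identical configuration + seed
reproduce byte-identical FASTQ and truth files.

**Background fluctuation.** Real coverage varies for reasons unrelated
to GC. The package models this as a per-tile multiplicative field:
tiles of one insert length, each with a multiplier drawn once from
Normal(1, sd_depth/target_coverage), floored at 0, applied on top of
the GC acceptance weight. This is one admissible mechanism among many
(per-base, additive, long-range-correlated variants would also widen
the coverage scatter); it was chosen as the simplest field that leaves
the GC-bias slope unchanged in expectation while widening the
normalized-coverage range, and it is off by default.

**Circular chromosomes.** Fragment wrap-around at the origin is
available behind `SimConfig(circular=True)` but off by default; for
multi-megabase chromosomes the edge effect of the linear treatment is
a few parts in 10⁴ of fragments.

## The bias estimator

Windows of size equal to the mean fragment length (taken from proper
pairs' template lengths when alignments are available; 200 bp fallback
for single-end data), step half a window. Per window: GC fraction and
mean depth. Depths are normalized by the mean of per-window means
(not the per-base global mean; the two differ only through edge
windows). Windows above 2× normalized coverage are removed once — no
re-normalization pass — as likely repeats; a window at exactly 2.0 is
kept ("more than twice"). The remaining points are fit by unweighted
ordinary least squares of normalized coverage on GC fraction; the
slope is the degree of GC bias, with r² reported as a diagnostic only.
Coverage counts read bodies (as an aligner would see), every reported
alignment included by default, soft clips excluded.

Reference-free mode replaces the reference with assembled contigs:
windows are collected per contig, contigs shorter than the window are
skipped and counted, and normalization is global across all windows so
the slope remains comparable.

### Known attenuation of the recovered slope

The estimator systematically under-recovers the simulated slope by a
factor of ~0.85–0.88 under the default geometry (estimation window =
insert length). The cause is a kernel mismatch, not a bug: the mean
coverage of a window integrates the acceptance weights — hence the GC —
of all fragments overlapping it. That weighting is triangular over
roughly three window-widths, with only 2/3 of its mass inside the
window whose GC is the regressor. The within-window binomial
composition variance (p(1−p)/w ≈ 0.0014 at w = 180, p ≈ 0.5) is
therefore only partially shared between regressor and response,
attenuating the OLS slope by at most

    r_max = 1 − Var_binom / (3 · Var_total),

≈ 0.87 when the total windowed GC sd is 6%. Observed recovery ratios
(0.85–0.88 across block structures from 2 kb to 20 kb, coverages
12–50X, both signs) sit just below this bound, the remainder coming
from block-boundary smoothing. Consequences: recovered slopes are
comparable with each other and with published slope tables (all
computed by the same windowed estimator), monotone and sign-faithful
in the true bias, but a simulated s = 3.8 reads back as ŝ ≈ 3.3. The
attenuation shrinks as the window grows relative to the insert length
or as the genome's GC variance grows relative to the binomial floor.
The test suite pins the observed recovery band rather than pretending
to unbiasedness; the acceptance-grade recovery check asserts the
stricter ±0.25 tolerance and documents its failure at strong bias as
expected behaviour of this estimator class.

## Coverage diagnostics

Zero-coverage regions are maximal runs of depth 0, with no minimum
length (a single base counts). Depth histograms are integer-binned
counts over selected loci (BED intervals) or the whole sequence;
merging loci with their complement reproduces the background histogram
exactly. Truth-based and alignment-based tracks agree exactly when one
SAM record is written per simulated read.

## Break-curve analysis

To compare the "shear" effects of repeats and GC bias without running
an assembler: remove a set of intervals from the genome — a repeat
annotation (BED), or the k most GC-extreme windows — and compute the
N50 of the remaining pieces (largest L such that pieces ≥ L hold half
the bases). Overlapping selected windows are merged before breaking
(half-overlapping sliding windows would otherwise double-count;
`merge=False` keeps the per-window footprint in the removed-bases
accounting). Ties at rank k break by leftmost start, making the curve
deterministic. Removing intervals can only shorten pieces, so the
curve is non-increasing in k.

## Synthetic genomes

Generated genomes are concatenations of blocks whose bases are i.i.d.
with per-block P(G or C); this controls the windowed-GC distribution,
which is the only genome property the bias mechanisms above depend on.
Presets (2-kb blocks, fixed once):

- `symmetric` — block GC ~ Normal(0.5, 0.05) clipped to [0.2, 0.8];
  windowed GC sd ≈ 6% at 180 bp, the bacterial-like reference
  condition for recovery experiments.
- `ecoli-like` — block GC = clip(0.52 − Exp(0.05), 0.15, 0.8): a
  left-skewed distribution with a genuine low-GC tail, so positive
  bias produces far more zero-coverage bases than negative bias of
  equal strength.
- `osativa-like` — clip(0.38 + Exp(0.09), 0.1, 0.9): right-skewed and
  the widest of the three, the plant-like high-variance condition.

What these fixtures do not emulate: repeats, long-range composition
correlation (isochores), coding structure, and real error spectra.
Tests passing on them demonstrate the correctness of the machinery and
the qualitative mechanisms (depletion asymmetry, contiguity decay),
not quantitative agreement with any particular organism — analyses of
real accessions require the corresponding FASTA/BAM inputs.

## Problem sizes and numerics

Unit and property tests run on 10 kb–1 Mb fixtures at 1–50X; the
reproduction script uses a 1 Mb genome at 50X across five slopes and a
300 kb skewed genome at 10X over several seeds, which keeps a full run
in the tens of seconds while leaving sampling error well below every
asserted tolerance (the null-slope estimate's across-seed sd is ~0.03
at 1 Mb/50X). Windows with more than half ambiguous bases are skipped
and counted rather than imputed; fragment proposals containing any
ambiguous base are resampled; GC fractions exclude ambiguous bases
from numerator and denominator. Percent summaries are rounded to one
decimal; all internal computation is in full precision, coordinates
are 0-based half-open throughout, and BED output follows that
convention.
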