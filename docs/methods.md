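# Methods

## Scope and model

`macall` analyzes mutation-accumulation (MA) assays in haploid microbes:
many independent lines derived from one ancestor are repeatedly
bottlenecked to single colonies so that spontaneous mutations fix nearly
neutrally, then whole-genome sequenced. The package consumes the
post-alignment abstraction of such an experiment — per-site read-count
configurations (A, a, C, c, G, g, T, t; uppercase forward strand,
lowercase reverse) for each line under two independent aligner views,
plus per-aligner indel-evidence records — and produces mutation calls,
rates, spectra, positional tests, clustering statistics and an effective
population size. Read alignment itself is out of scope; the two
"aligners" are abstract views whose agreement is a filter against
aligner-specific artifacts.

All coordinates are 1-based and inclusive; the chromosome is circular
and distances are measured on the circle.

## Consensus mutation calling

A base-pair substitution (BPS) is called at a site in a focal line when:

1. the focal line's consensus base (its most frequent base, requiring
   ≥ 80% of the line's reads; ties yield no consensus) differs from the
   consensus of all other lines, defined as the base carried by ≥ 80% of
   the other lines' own per-line consensus calls;
2. the focal base is supported by ≥ 2 forward and ≥ 2 reverse reads;
3. both aligner views independently satisfy (1)–(2) with the same
   alternative base;
4. the site has depth ≥ 10 in both views. Sites failing the depth
   threshold (or lacking an others-consensus) are excluded from both
   calling and the per-line analyzed-site count *n_i*.

Consensus indels require identical (position, type, size, motif)
evidence from both aligners, each with supporting reads ≥ 30% of the
spanning reads and ≥ 2 forward / ≥ 2 reverse support. Long events from
paired-end realignment evidence use ≥ 6 forward, ≥ 6 reverse and ≥ 20
supporting reads in total. Any identical event shared by strictly more
than 50% of lines is removed as a progenitor variant or assembly error;
the rule is applied to BPSs and indels alike, since both inherit the
same two failure modes. All thresholds live in `CallingThresholds`;
the 30%/2F/2R/>50%/6-6-20 values are standard MA-pipeline practice,
and the 80%/depth-10 BPS-side values mirror the indel logic.

## Rates

Per line, μ = m / (nT) with SE √(μ/(nT)) = √m/(nT) (Poisson counting
error), where m is the event count, n the analyzed sites and T the
generations. Pooled across N lines: the mean of per-line rates with
SE = s/√N, s the sample (N−1) SD. Per-genome rates multiply the
per-site rate by the analyzed-site count, not the raw genome length.
Generation totals use the harmonic mean of cell divisions per transfer
(divisions read off colony counts as log₂ CFU) times the number of
transfers: the harmonic mean is appropriate because a transfer with few
divisions throttles the whole line's accumulation.

## Spectrum

Substitutions collapse into six strand-symmetric classes; transitions
exchange purine↔purine or pyrimidine↔pyrimidine; a change is A/T-ward
when the ancestral pair is G:C and the derived pair is A:T or T:A.
Conditional class rates divide by the genome's A:T or G:C site count
(whichever the class is sourced at) times total line-generations.
Indels are short at 1–3 bp and long at ≥ 4 bp. Nucleotide loss/gain per
generation per line divides summed deletion/insertion lengths by ΣT_i.
Pooled Ts/Tv (total transitions over total transversions) and the mean
of per-line ratios are both reported and labeled: they differ, and the
per-line mean is computed only over lines with ≥ 1 transversion (the
ratio is undefined otherwise). The deletion-bias test is a Pearson
goodness-of-fit χ² of (deletions, insertions) against an equal split of
the indel total, with no continuity correction — with Yates' correction
the canonical 73-vs-33 table would give 14.35 rather than 15.09, so the
uncorrected statistic is the one this analysis tradition uses.

## Genomic context

The coding-distribution test compares coding/noncoding BPS counts to an
expectation proportional to coding/noncoding site totals (χ², df 1).
The NS/S test enumerates all 3L single-nucleotide changes over all
coding sites under bacterial translation table 11, unweighted by the
observed spectrum (a spectrum-weighted variant is available via the
`weights` argument), classifies observed coding BPSs by their actual
codon change, and applies the 2-cell χ². Changes to or from stop codons
count as nonsynonymous; codons containing non-ACGT characters are
skipped with a warning; a site inside overlapping genes counts once,
classified by the first containing gene.

BPS density is tallied in consecutive fixed-size bins (default 50 kb,
final partial bin kept; a 5.19-Mb genome tiles into 104 bins). The
terminus statistic is a one-sample t of the bin-count distribution
against the terminus bin's count: t = (x_term − mean)/(SD/√K), df =
K − 1. This construction is an interpretation — df = K − 1 matches the
published degrees of freedom — and because such tests are sometimes
computed with the focal bin excluded from the background, the
exclude-terminus variant is also computed and labeled.

## Multinucleotide mutations

Two deliberately distinct constructs. The detector groups each line's
events by consecutive circular distance: a cluster is a maximal run
whose successive gaps are all strictly < the window (20/50/100 nt);
runs of ≥ 3 count as one cluster. The expectation model tiles the
genome into ⌊G/w⌋ non-overlapping windows, takes λ = total_bps / G /
n_lines × w as the per-window Poisson rate, and returns
1 − P(X ≤ 1; λ)^n_windows (evaluated via `logcdf` and `expm1` to keep
precision at λ ~ 10⁻⁴). A Monte-Carlo oracle draws a Poisson(λ·n_windows)
event count per replicate line, scatters the events uniformly, and
reports the fraction of replicates with a doubly-hit window, with
binomial SE. Note the analytic formula evaluated at the canonical
parameter set (779 BPSs, 5.19 Mb, 47 lines, 50-nt windows) gives
1.32×10⁻³; this is the value the package stands behind.

## Effective population size

For haploids under neutrality, π_S = 2·Ne·μ, so Ne = π_S/(2μ). π_S is
measured on a codon-aligned strain set at four-fold degenerate third
positions whose first two codon bases are identical (and unambiguous)
across all sequences — the conservative silent-site filter — as the
mean over eligible sites of the fraction of sequence pairs differing
there. Gaps or ambiguity codes exclude a site.

## Synthetic data

The generator emulates the study conditions as defaults: 47 lines,
3,025 generations, a 5.19-Mb circular genome at 51% GC with ~85% coding
density, ~100× coverage, and mutation totals matching the observed
marginal counts (779/33/73). Coverage is Poisson per site, strand split
Binomial(depth, ½), and sequencing error (default 1%, the stress end of
short-read error rates) substitutes a uniformly chosen other base.
Indels do not perturb site counts (spanning reads still pile up on
reference coordinates); they emit evidence records with support drawn
as Binomial(spanning, 0.95), routed to the paired-evidence channel when
≥ 11 bp (beyond the reach of gapped short-read mapping). The two
aligner views are identical except at sites (or indel records) hit by
the configurable discordance probability. Not modeled: mapping bias,
GC-coverage bias, contamination, indel-induced coverage loss, and
error-generated indel evidence — so recovery tests demonstrate the
correctness of the calling logic under the stated noise model, not
robustness to real alignment pathologies.

The fixture catalog expands the published marginal totals into a
concrete 885-event catalog via deterministic rules (largest-remainder
class splits, even per-line allocation carrying the reported maxima,
minimal indel sizes with residual-absorbing long events, reserved
well-separated cluster coordinates: one BPS triple plus 17 pairs across
16 lines). Its marginal statistics — and only those — are meaningful.
The deleted-nucleotide total (14,061) is back-computed from the
published per-generation loss rate; the inserted total (80 nt) from the
published loss/gain fold; integer totals cannot satisfy both printed
values simultaneously (the fold evaluates to 175.76), a rounding-level
tension noted rather than hidden.

## Problem sizes and numerics

Tests and the acceptance script run the caller on a 10⁵-site genome
with 10 lines (the simulation design scales per-site costs linearly, so
this exercises every code path of the full-genome configuration), the
rate-recovery check at 200 replicates of 47 Poisson line counts, and
the MNM Monte Carlo at 10⁴ replicates. Degenerate inputs are errors,
not silent defaults: zero-variance bins, empty others-consensus,
all-coding genomes, zero eligible silent sites and inconsistent fixture
marginals all raise. Ties in consensus calling yield no call.
Undefined ratios (Ts/Tv with zero transversions, loss/gain fold with
zero insertions) are flagged as absent rather than infinite.
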