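# Methods

## Data model and conventions

Segments live internally in 0-based half-open coordinates, so length is
`end − start` with no off-by-one arithmetic; the canonical TSV dialect and
all report output use 1-based inclusive coordinates, matching how CNV locus
tables are conventionally printed (a locus printed as start *s* with length
*L* occupies 1-based positions *s* … *s*+*L*−1). BED export is 0-based
half-open.

A segment is a CNV relative to expected ploidy: 2 on autosomes and on the
female X, 1 on the male X outside the pseudo-autosomal regions. Losses and
gains are defined against that same baseline, so a male X segment at copy
number 2 is a *gain*. Male X segments intersecting a PAR by ≥ 1 bp are
excluded from the male-X stratum entirely rather than trimmed — no trimming
rule is defensible without probe-level data, and whole-segment exclusion is
the conservative choice. PAR coordinates default to the hg19 X PAR1/PAR2
intervals and are configurable in the genome model, since PAR boundary
conventions differ between builds and annotation sources. Y-chromosome
segments are never analyzed. Segments are atomic: a segment is in or out of
a stratum as a whole.

## Sample QC

Per cohort (cases and controls separately, or any configured grouping), the
cutoff is `2·median − min` of per-sample segment counts; samples strictly
above it are excluded. The even-length median is the midpoint of the
central pair, so the cutoff may be fractional. Counts default to *all*
segments attributed to a sample; a `min_size` option restricts counting to
segments above the size floor, since it is ambiguous whether sub-10 kb
segments should contribute. QC is single-pass by design: recomputing the
cutoff on an already-filtered cohort can legally exclude further samples,
so the pipeline never iterates it.

## Burden testing

Each stratum × direction gives a 2×2 table of *segment* counts (not carrier
counts): rows cases/controls, columns large (> 100 kb) / small (10–100 kb),
with both size boundaries strict in the "greater than" sense (a segment of
exactly 10 kb is sub-threshold; exactly 100 kb is small). The p-value is
the exact hypergeometric tail with all margins fixed, computed via
`scipy.stats.hypergeom`; one-sided "greater" is the default (the hypothesis
is an *excess* of large CNVs in cases). The two-sided variant uses the
"minlike" rule (sum of point masses ≤ the observed mass) with a 1+1e-10
relative guard against ties lost to floating point.

The reported odds ratio is the unconditional sample (cross-product) OR,
which is what published burden tables print; the conditional-MLE OR is
available (`conditional_mle_odds_ratio`) but not default. Tables with a
zero cell flag the OR undefined by default; the Haldane–Anscombe +0.5
correction is opt-in. Bonferroni correction divides the family-wise alpha
by the number of tests actually run in the invocation (three strata at
alpha 0.05 → 0.0167).

## Permutation association

Qualifying segments (≥ 5 markers and span ≥ 10 kb, both inclusive) are
translated into pseudo-markers: one per unique (chromosome, breakpoint,
direction). A sample carries a marker iff one of its same-direction
segments satisfies `start ≤ position ≤ end` — closed containment, so a
segment carries both of its own breakpoints. This single rule is equivalent
to evaluating end-breakpoints at `position − 1` on the half-open interval
and stays well-defined when one position is simultaneously a start and an
end of different segments.

The test statistic is the case carrier count. Under uniform relabeling with
the case count fixed, its distribution is exactly
Hypergeometric(n, K carriers, n_cases); Monte-carlo mode therefore samples
that distribution directly with a seeded `numpy` generator — statistically
identical to shuffling labels, at a fraction of the cost. Exhaustive mode
literally enumerates all C(n, n_cases) label assignments (guarded at 10^6)
and returns the exact tail fraction, which equals the one-sided Fisher p of
the carrier table; the test suite asserts both the MC/exhaustive agreement
and that identity. The empirical p uses the +1 correction (R+1)/(N+1),
whose floor at 100,000 permutations is 1/100,001 (printed `1.0E-5`). Note
the floor interacts with the genome-wide threshold 5e-5: at least ~20,000
permutations are required before any marker *can* pass it.

Each marker's generator seed derives from (master seed, chromosome,
position, direction) via a CRC hash, so results are independent of
traversal order. Loci are maximal runs of consecutive significant markers
with the same direction and an *identical* carrier set; requiring set
identity (not just overlapping significance) prevents chaining unrelated
events into one locus. The X chromosome is tested separately within each
sex, because carrier definitions and baseline ploidy differ.

## Familial shared regions

Per (chromosome, direction), breakpoints of qualifying segments (> 10 kb)
partition the axis into atomic intervals with constant carrier sets. A
shared region is a maximal run of contiguous atomic intervals whose
*affected* carrier set is identical throughout, has ≥ `min_affected`
members, and over which at most `max_unaffected` distinct unaffected
members have any overlapping same-direction segment. Requiring an identical
affected set guarantees the reported invariant that every listed affected
individual carries the *whole* region; the alternative (count-only
plateaus) can report regions no single individual spans. The consequence —
a 4/0 plateau inside a longer 3/0 stretch yields separate adjacent loci —
matches how per-threshold locus tables are presented. Unaffected relatives
genotyped within families count toward the unaffected tally; external
controls do not. Cross-cohort overlap is any ≥ 1 bp same-direction
intersection; no reciprocal-overlap fraction is imposed.

## Synthetic cohorts

The generator emulates the statistical structure the analyses consume, at
the study's scale by default (70 cases, 51 male; 605 controls, 382 male):

- **Counts**: per-sample autosomal segment counts are negative binomial
  (default mean 25, dispersion 10 — tens of called segments per array with
  overdispersion); per-sex X counts are Poisson (default mean 12 for males,
  2 for females, the approximate per-male X segment load implied by
  hundreds of X segments per few hundred males).
- **Lengths**: log-normal with μ = ln 20 kb, σ = 1, truncated below at
  1 kb via inverse-CDF sampling — a heavy right tail in which ~7% of
  >10 kb segments exceed 100 kb, i.e. large events are a minority. The
  parameters are exposed and were chosen for qualitative realism, not
  fitted to any dataset.
- **Enrichment**: the male-case X enrichment multiplies the *odds* that a
  segment's length falls in the large class by θ, leaving the conditional
  length distribution within each class untouched. This plants exactly the
  quantity the burden table estimates, so the expected sample OR equals θ
  and recovery is a clean calibration check.
- **Planted loci**: fixed-coordinate segments inserted per sample with
  Bernoulli(f_case / f_control) membership; marker counts are
  deterministic, `max(1, round(length / 1800 bp))`, approximating the probe
  density of a ~1.8 M-marker SNP array so the ≥ 5-marker filter bites.
- **Families**: each family emits affected/unaffected members with
  background segments plus planted shared segments in affecteds. Breakpoint
  jitter erodes each planted interval *inward* by uniform 0..j bp per end,
  so the shared core always lies inside the planted interval and contains
  the doubly-eroded core — symmetric jitter cannot guarantee either bound
  deterministically.

What the simulator does **not** model: raw probe intensities and calling
noise, common copy-number polymorphism structure, breakpoint clustering at
segmental duplications, LD, or relatedness beyond shared planted segments.
Passing recovery tests therefore demonstrates correctness of the downstream
statistics under the stated generative assumptions, not robustness to
array-calling artifacts.

## Numerical choices

- Report rounding is half-away-from-zero (so 56.625 → 56.63), since
  binary banker's rounding disagrees with printed tables at ties.
- Small p-values print in compact exponent form (`1.0E-5`).
- Degenerate tables (any margin zero) return p = 1; zero-cell ORs are
  flagged rather than silently corrected.
- All simulation and permutation randomness flows through
  `numpy.random.default_rng` seeds; reruns are byte-identical.

## Problem sizes in the test and acceptance runs

Exact-test verification enumerates all 635,376 2×2 tables with N ≤ 60
against an integer-arithmetic oracle. Permutation calibration uses cohorts
of ≤ 8 samples (exhaustive vs 10^5 Monte-carlo draws) and 500 null markers
at 70 vs 605 samples with 999 permutations each. Enrichment recovery runs
200 replicates per θ ∈ {1.5, 2.5, 4} on a scaled all-male cohort of 200
samples with 12 X segments per male. Shared-region verification uses 40
random instances of ≤ 50 segments against a unit-interval oracle. These
sizes give stable medians and tight binomial bounds while keeping the full
suite in the low minutes.

## Known limitations

- Published locus tables contain internal inconsistencies (odds ratios that
  do not match their own printed carrier counts, and two chr21 loci whose
  printed coordinates abut rather than overlap); only internally consistent
  rows are used as verification anchors, and the abutment is asserted
  as-is.
- The QC rule's cohort granularity and its treatment of sub-10 kb segments
  are configurable because the original description leaves both open.
- No CNV calling from intensities, no build liftover, no symbolic-allele
  VCF parsing, no linkage computation; linkage regions enter only as
  interval inputs to annotation.
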