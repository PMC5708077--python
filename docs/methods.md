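# Methods

`cnvarray` implements a case/control copy-number-variation (CNV) analysis
for array-CGH data: per-probe log2 ratios in, disease-associated CNV
regions and validation statistics out. Because the analysis is defined on
probe grids and log2 ratios rather than raw images, every stage can be
exercised end to end on simulated cohorts with known truth.

## Signal model and the synthetic cohort

A two-channel aCGH probe reports log2 of the sample/reference copy-number
ratio. Against an idealized diploid reference the expectations are

| state                | copies | log2 expectation |
|----------------------|--------|------------------|
| diploid background   | 2      | 0                |
| heterozygous loss    | 1      | log2(1/2) = −1   |
| single-copy gain     | 3      | log2(3/2) ≈ +0.585 |
| homozygous loss      | 0      | −∞, capped at −3 |

The homozygous-deletion cap (configurable, default −3.0) mimics residual
background hybridization; a multiplicative `attenuation` factor in (0, 1]
models the signal compression of real hybridizations. The default of 1.0
keeps noiseless profiles analytically checkable — a deliberate trade of
realism for verifiability; lowering it stresses the caller the way a
compressed real array would.

Probe noise is i.i.d. Gaussian with sd `noise_sd` (default 0.15 in log2
units, the middle of the QC band below). Carrier status for each truth
CNV is Bernoulli per sample at the configured group frequency, drawn from
a cohort-level stream; per-sample noise comes from substreams spawned
deterministically from one seed, so a cohort is bit-reproducible and the
carrier pattern does not depend on the probe grid.

What the simulator deliberately does **not** model: dye-swap/replicate
structure, GC/wave artifacts, reference-sample polymorphisms, probe-
specific response, and correlated noise. Passing tests therefore show
that the analysis logic is correct under the stated noise model, not that
it is robust to every array artifact; on real data the DLRS-based sigma
estimate absorbs part (only part) of such effects.

Probe maps are laid out at roughly even spacing — ~7 kb emulates a
genome-wide 400K-probe design, 205 bp the fine custom tiling — with
optional uniform jitter; a chromosome of length L at spacing s carries
⌈L/s⌉ probes.

## QC: derivative log ratio spread

DLRS is the robust spread (IQR/1.349 by default; plain sd optionally) of
consecutive-probe log2-ratio differences within chromosomes, divided by
√2. For i.i.d. noise of sd σ the differences have sd σ√2, so DLRS
estimates σ while being insensitive to step changes from real CNVs.
Arrays pass QC when DLRS < 0.30 (strict); well-behaved arrays land near
0.11–0.17. The per-sample DLRS is also the default noise scale σ for
calling.

## Aberration calling

The caller scores an interval of N probes as

    score = |mean log2| · √N / σ ,

a z statistic against the no-change null, and uses threshold 6.0 by
default. Per chromosome it finds the maximal-scoring interval by
exhaustive search over all O(n²) intervals, extracts it, and recurses on
both flanks until nothing reaches the threshold. Ties are broken toward
the longer, then leftmost interval, making extraction deterministic.
Surviving calls must pass one of the two aberration filters:

* **standard** — ≥ 3 probes and |mean log2| ≥ 0.25 (burden analyses);
* **correlation** — ≥ 2 probes and |mean log2| ≥ 0.5 (association
  analyses).

Raising the threshold can only remove calls (the greedy extraction is
threshold-monotone), and on instances small enough to enumerate the
decomposition equals a brute-force oracle exactly. The exhaustive search
is quadratic in probes per chromosome; the vectorized implementation is
comfortable to a few thousand probes per chromosome, which sets the
demonstration genome's scale. Filters are applied at the call level
(probe minimum = call length), since per-probe thresholds are not part of
the interval-score contract. A single per-sample σ is used; per-probe
error weights are not modeled.

## Burden comparison

Per-sample counts of total/gain/loss calls (optionally per chromosome)
are compared between groups with the two-sided Wilcoxon rank-sum test:
mid-ranks for ties; for small groups (either side < 8) the exact
permutation distribution of the rank sum, computed by exact subset-sum
counting over doubled (hence integer) mid-ranks; otherwise the normal
approximation with tie-corrected variance and 0.5 continuity correction.
The exact and approximate branches agree to within 0.02 for the bulk of
instances at group sizes 8–12 (95th percentile); extreme tied tails can
differ by a few hundredths, which is inherent to the discrete/continuous
comparison, and the approximation keeps the empirical two-sided type-I
error at α = 0.05 within [0.04, 0.06] on null Poisson simulations. No
multiple-testing correction is applied across chromosomes by default,
mirroring per-test reporting; a Benjamini–Hochberg option exists.

## CNV regions and two-stage selection

Per-sample calls of the same kind (gains never merge with losses) are
merged into regions by single-linkage reciprocal overlap: two intervals
link when shared bp / max(length) ≥ 0.5 (parameter). Because a merged
region's span is the union of its members, one pass is not idempotent;
passes are repeated until a fixed point, so merging its own output
changes nothing. Region carriers are the union of member samples, split
by group.

Selection keeps regions with length ≥ 1 kb whose case carrier count
strictly exceeds twice the control carrier count (zero control carriers
pass with any case carrier). Counts, not frequencies, are compared by
default — with 48 cases vs 24 controls a count ratio of 2 happens to be
frequency parity, and a frequency mode is provided for other designs.
Survivors split at 10 kb: smaller regions are carried to the final set
without re-testing (flag-controlled), larger ones are re-evaluated in an
independent cohort on a 205 bp tiling restricted to the candidates plus a
10% flank per side (allowing boundary refinement), re-called with the
correlation filter, re-merged, and re-selected under the stage-2 group
sizes (40/40 in the demonstration).

The demonstration truth set holds 10 disease-associated CNVs
(case/control frequencies 0.25/0.05; five < 10 kb, five ≥ 10 kb) and 10
null CNVs (equal frequency 0.20, all ≥ 10 kb). Nulls sit in the re-tested
size class by design: under the unbalanced stage-1 cohort an
equal-frequency CNV lies exactly on the count-ratio boundary and passes
stage 1 about half the time whatever its frequency, so only the balanced
second stage can reject it — which is precisely the role of the
validation cohort.

## Region annotation

A region is *exonic* if it overlaps ≥ 1 bp of any exon, else *intronic*
if it overlaps any gene span, else *intergenic*; the exon > intron
precedence applies across all overlapping genes, and every region gets
exactly one label. No minimum-overlap fraction is imposed — "contains
exon sequence" is the criterion. Gene models come from BED12 (blocks =
exons) or GFF3 (gene/exon features; 1-based inclusive, converted on
read); overlapping transcripts collapse to union exons. Typed non-coding
elements (repeats, CpG islands, lincRNAs, DNase-hypersensitive sites,
TF-binding sites) are reported as the set of types overlapped; the
synthetic track generator emits the same BED formats real UCSC/ENCODE
exports use, so real tracks drop in.

## Co-occurrence clustering

The binary region × sample carrier matrix is clustered row-wise by
complete-linkage agglomeration on Hamming distance, both implemented in
the package so merge order is fully specified (minimum-distance pair
first; ties to the lowest cluster indices). Complete linkage guarantees
non-decreasing merge heights. Cutting at height 0 — the default — groups
exactly the regions with identical carrier patterns, the only
parameter-free notion of a co-occurring block; the cut height is exposed
for looser blocks. A block reports its member regions, its supporting
samples (those carrying *every* member), and its maximal intra-block
distance. Columns (samples) are not clustered: blocks are defined over
regions.

## Validation statistics

Genotype tables (no/het/hom deletion counts per group) collapse to 2×2 in
two exposure modes — homozygous deletion vs rest, or any deletion vs
none — giving OR = (a·d)/(b·c) with cases in the top row. Any zero cell
triggers the Haldane–Anscombe +0.5 on all four cells before both the
point estimate and the interval. The default 95% CI is Woolf's
log-normal interval exp(ln OR ± 1.96·√Σ1/cell); a conditional exact
interval (via the noncentral hypergeometric) is available, since no
single CI convention is universal for small tables. The two-sided Fisher
exact p sums, in exact integer arithmetic, the hypergeometric
probabilities not exceeding the observed table's. Sequencing-report
coordinates are 1-based inclusive (span = stop − start + 1); converters
to the package's internal 0-based half-open convention are provided.

## Numerical and scale choices

- Interval-score ties use a 1e-12 relative tolerance before the
  longer/leftmost tie-break; test instances use dyadic-grid ratios so
  partial sums are exact and implementations comparable bit-for-bit.
- The demonstration genome is 4 × 1 Mb at 500 bp spacing (2,000 probes
  per chromosome, 72 + 80 samples), chosen so the exhaustive caller runs
  the full two-stage analysis in about a minute; the QC simulation uses
  10⁵ probes per sample, where DLRS concentrates within 2% of σ.
- Exact rank-sum is capped at pooled n = 50, keeping subset-sum counts
  inside float64's exact-integer range.
- Degenerate inputs fail loudly: empty groups, zero group totals,
  non-positive σ, single-probe chromosomes, stage-2 cohorts sharing
  samples with stage 1, truth CNVs of opposite kind overlapping.

## Known limitations

- The interval score assumes exchangeable Gaussian noise within a
  sample; correlated or wavy baselines would inflate calls and are
  upstream-correction territory.
- Exhaustive O(n²) search is not suitable for hundreds of thousands of
  probes per chromosome without windowing.
- The greedy decomposition is locally optimal per extraction, not a
  global segmentation optimum; for well-separated CNVs (the regime here)
  they coincide.
- Odds-ratio validation treats truth genotypes as if PCR-verified;
  genotype-calling error from depth-of-signal is not modeled.
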