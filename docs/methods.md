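# Methods

This note documents the statistical models implemented in `autozyg`, the
choices made where the underlying methods literature leaves latitude, what the
synthetic-data generators do and do not emulate, and the package's known
limitations. No empirical value is quoted here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and coordinates

Genotypes are stored as counts of a per-marker *counted allele* (the allele-1
column of a PLINK .bim), never re-polarized; `-1` is missing. Physical
coordinates are 1-based inclusive throughout; anything exported as BED is
converted to 0-based half-open in exactly one function (`to_bed_interval`).
When a map carries no genetic positions they are imputed at 1 cM/Mb and the
imputation is flagged — the HBD, Ne and XP-EHH stages all consume these
distances, so with an imputed map their "Morgans" are really rescaled
megabases. The PLINK text dialect cannot carry the counted-allele designation
for markers without any heterozygote (no allele columns exist in .map); the
reader recovers designation from heterozygote order (this writer emits
counted-allele-first heterozygotes) and falls back to the lexicographically
smaller allele. The binary dialect round-trips exactly in all cases and is the
format of record.

## QC

Samples failing the missingness threshold (default >0.10) are removed first;
markers are then classified in the fixed order sex-chromosome → call rate
(<0.95) → MAF (<0.05) → Hardy–Weinberg (exact conditional test, remove when
p < 1e-5), so each marker lands in at most one category and the ledger
conserves: initial = remaining + Σ removals. Marker statistics are computed on
post-sample-removal data. The HWE test conditions on the observed allele count
and sums the probabilities of all heterozygote counts no more likely than the
observed one (no mid-p correction). Re-applying the filters to survivors
removes nothing (idempotence is a tested property).

## Runs of homozygosity

A run is a maximal stretch of consecutive markers for one individual and
chromosome with at most 1 heterozygous and 1 missing call, at least 15 SNPs
and at least 1 Mb from first to last marker (all four bounds configurable).
"Maximal" refers to the composition constraints only; the SNP-count and length
filters are applied afterwards. Around an allowed heterozygote two maximal
windows can overlap; the longer window wins, ties to the leftmost, making the
output deterministic and non-overlapping. Run length is last-marker minus
first-marker bp (no +1); length classes are half-open [lo, hi) with bounds
0–3–5–10–20–30–∞ Mb.

F_ROH divides each individual's summed run length by a configurable autosome
length (default 2399.4 Mb, the goat autosome). F_HOM uses the expected
homozygosity per marker 1 − 2pq·2n/(2n−1) — the small-sample-corrected
heterozygosity, with p and n from the marker's non-missing genotypes — and
reports (O−E)/(N−E); it is undefined (NaN) when every marker is monomorphic.
Per-chromosome ROH coverage divides the mean summed run length *among
carriers* (individuals with ≥1 run on that chromosome) by the chromosome
length; a chromosome with no runs reports 0 by convention. ROH islands are
maximal stretches of consecutive SNPs whose run-coverage share across
individuals exceeds a threshold (default 45%).

Detection bias worth knowing: a run extends past a true autozygous tract until
its heterozygote/missing budget is exhausted — about 2/h markers in total at
per-marker heterozygosity h — so F_ROH slightly overestimates planted
autozygosity (≈0.01 at the default test geometry). The planted-recovery test
budgets for this; it is inherent to the consecutive-run definition, not a
defect of this implementation.

## HBD hidden-Markov model

Each individual genome is a mosaic over K classes (default 10): K−1 HBD
classes with fixed rates R_k = 2^1 … 2^(K−1) per Morgan and one non-HBD class
sharing the oldest rate. Segment lengths are exponential with rate R_k, so the
transition over distance d is stay-with exp(−R_k d), otherwise re-draw the
class from the mixing distribution M (self-re-entry allowed). Emissions: HBD
classes emit a heterozygote only through genotyping error ε (default 0.001,
configurable; the methods literature for this model family does not pin it)
and homozygotes in proportion to allele frequency; the non-HBD class emits
Hardy–Weinberg frequencies; missing genotypes emit 1 in every class. Only M is
estimated — per individual, by EM on scaled forward–backward recursions that
exploit the diagonal-plus-rank-one transition structure (the sufficient
statistic is the expected count of segment-change draws landing in each
class). Convergence at log-likelihood gain < 1e-6, cap 1000 iterations,
uniform initialization; non-convergence returns a flagged result. Monomorphic
markers carry no HBD information and are dropped before fitting. Allele
frequencies come from the analyzed sample. F_G–T sums genome-averaged
posterior autozygosity over HBD classes with R_k ≤ T and is non-decreasing in
T by construction.

## LD-based Ne

r² is the squared Pearson correlation of unphased genotype dosages over
pairwise-complete observations (composite LD). Within-chromosome pairs are
binned by genetic distance on a log grid over [0.0005, 0.25] Morgans (20 bins
by default), restricted to MAF ≥ 0.05 within the analyzed population. The
sample-size adjustment subtracts 1/(2n) from each bin mean (on by default).
Note the sampling floor of *dosage* r² with n individuals is 1/(n−1), roughly
twice 1/(2n) — the 1/(2n) convention is retained as the documented default of
the tool family this mirrors, and the constant-size recovery test passes with
it; users wanting a sharper ancient-Ne correction can subtract their own floor
via `adjust="none"`. Each bin reports Ne = (1/r²_adj − 1)/(4c) at the bin
midpoint and the generation T = 1/(2c); bins with r²_adj outside (0,1) report
Ne as missing rather than a negative number.

## Differentiation and structure

The pairwise coancestry θ between two populations is a method-of-moments
pure-drift estimator aggregated as a ratio of sums over markers: the numerator
removes each sample frequency's binomial sampling variance from (p̂₁−p̂₂)², the
denominator adds back the corrected within-population heterozygosities so it
estimates 2p̄q̄. The Reynolds distance is −ln(1−θ) of the same θ — the two
matrices the pipeline writes are exact transforms of each other. Per-marker
and global F_ST use the Weir–Cockerham (1984) a, b, c variance components with
observed heterozygosity; global is Σa/Σ(a+b+c). AMOVA decomposes squared
dosage distances (pairwise-complete) into among- and within-population
components via the standard sums-of-squares identities, with Φ_ST and a label
permutation p-value (+1 correction, default 100 permutations). LD pruning is
the PLINK `indep-pairwise` greedy rule (windows of 50, step 10, r² > 0.1
removes the lower-MAF member, ties drop the later marker). PCA mean-imputes
missing genotypes, centers per marker and scales by √(p(1−p));
variance-explained fractions are eigenvalues over the trace, invariant to
duplicating samples. The NJ tree is Saitou–Nei agglomeration on the 1−IBS
allele-sharing matrix averaged to population level; negative branch lengths
are clamped to zero with the deficit transferred to the sister branch so
patristic distances are preserved, and additive matrices are recovered exactly
(tested against scikit-bio's implementation as an independent oracle).

## Selection scan

Per-site nucleotide diversity is the unbiased pair proportion
2k(2n−k)/(2n(2n−1)) over the 2n non-missing allele copies. The diversity
contrast is oriented π_low/π_high, so diversity *loss* in the high-fecundity
group inflates the ratio and its upper tail defines the outlier; log2 of the
ratio is also emitted. ZF_ST standardizes per-SNP F_ST with the population
(n-denominator) standard deviation. EHH at extension x is the probability that
two random distinct haplotypes are identical at every marker between the core
(exclusive — EHH(core) = 1 by convention, as in the cross-population variant)
and x, computed jointly over all haplotypes of a population. XP-EHH is
ln(I_A/I_B) with I the trapezoid integral of EHH over Morgans in both
directions, truncated where the pooled-population EHH drops below 0.05 or the
physical extension exceeds 2.5 Mb; raw scores are standardized to mean 0,
variance 1 across cores. Outliers are the ⌈q·n⌉ largest finite values
(empirical top-q, default 1% for F_ST and π-ratio, 0.1% for XP-EHH); candidate
regions are outlier positions ±100 kb, merged when overlapping, clipped at
chromosome ends, and annotated by interval intersection when a BED/GFF gene
file is supplied.

## Synthetic data (what a green test establishes)

The generators state a world; they are not tuned to the detectors.

- **Chip geometry**: 2 chromosomes × 100 cM at 1 marker/50 kb (≈4,000
  markers), 1 cM/Mb, 50 diploids per population, genotyping error 0.001,
  missingness 0.01 — inside the default QC tolerances by design.
- **Balding–Nichols**: ancestral frequencies uniform on [0.05, 0.95],
  population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes
  Binomial(2, p). Backs the F_ST/Reynolds/PCA truth tests (θ̂ ≈ F).
- **Wright–Fisher**: forward diploid simulation, discrete generations, random
  mating, Poisson crossovers at 1/Morgan, independent-sites founders. Backs
  the Ne recovery and neutral-scan tests. It has no mutation, migration or
  overlapping generations; ancient bins reflect the independent founders
  rather than deep coalescent history, so only recent-generation bins are
  compared to the simulated N.
- **Outbred planting canvas**: independent Bernoulli haplotypes at
  frequencies uniform on [0.25, 0.75], mimicking the common-allele
  ascertainment of commercial arrays. At chip-wide frequencies spanning
  [0.05, 0.95], chance ≥1 Mb homozygous runs alone contribute up to 0.02
  F_ROH in fully outbred individuals — indistinguishable from signal for any
  detector — so the ascertained canvas is the world in which tract recovery
  is a meaningful test.
- **Planted autozygosity**: copies one haplotype over the other in
  non-overlapping tracts with truncated-exponential lengths, trimming the
  last tract so realized coverage equals the request; the truth set records
  realized intervals, and recovery is always judged against realized truth.
- **Planted sweep**: a configured fraction (default 0.9) of target-population
  haplotypes copy one founder haplotype over a contiguous window around the
  core with exponentially distributed left/right extents (mean 3 cM), so the
  per-marker copy probability decays with distance — a recent, near-fixed
  hard sweep. The two contrasted groups are split from a *single* simulated
  population: independent simulations have unrelated haplotype structure and
  an unrealistically noisy raw XP-EHH background, which no real pair of
  related breeds exhibits.

All generators are integer-seeded through `numpy.random.default_rng` and
byte-deterministic for a fixed seed.

## Numerical choices

- Forward–backward is per-site scaled (no log-space needed); posteriors are
  renormalized against drift at the 1e-12 level.
- The exact HWE test computes the conditional distribution in log space and
  includes float-ties (≤ observed·(1+1e-12)) in the tail.
- Quantile outliers use rank counts (⌈q·n⌉), not interpolated quantiles, so
  tie behavior is deterministic (earlier marker wins).
- NJ pair selection breaks Q-matrix ties by row-major order; branch-length
  clamping preserves path lengths.
- Degenerate inputs error loudly rather than returning silently wrong values:
  <2 complete pairs or zero variance for r², constant inputs for
  standardization, <3 taxa for NJ, all-samples-removed QC.

## Limitations

- The HBD EM is pure numpy and costs seconds per individual at 50K scale;
  cohort-wide fits are minutes, not seconds.
- AMOVA implements the two-level design only (no region/breed hierarchy).
- XP-EHH requires externally phased haplotypes; no phasing is attempted.
- Ne bins assume a single panmictic population per run; admixed samples
  violate the model and bias r² upward (Ne downward).
- The text PLINK dialect loses counted-allele designation for het-free
  markers (see Data model).
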