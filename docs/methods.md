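# Methods

This note documents the models behind `sdrscan`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data
experiments do and do not demonstrate.

## The genetic system being modelled

A young XY pair in a fish genome: X and Y are largely homomorphic and
assembled as separate contigs. Recombination is suppressed around the
sex-determining gene, producing a sex-determining region (SDR) on the Y
that is a mosaic of (a) Y-specific sequence with no X homolog —
hemizygous in males, absent in females — and (b) X–Y homologous but
diverged sequence. The SDG itself is a translocated, truncated duplicate
of an autosomal gene (four of the parent's seven exons retained, the
paradigm of a Y-linked *amh* duplicate), and LINE retroelements accumulate
around it.

## Synthetic-data generator

`simulate_genome` / `simulate_samples` (module `sdrscan.simulate`) draw a
multi-contig genome and n males + n females with depths and genotypes.
All randomness flows from a single integer seed through fixed per-stage
substreams (`SeedSequence(seed, spawn_key=(stage,))`), so identical
seed + config reproduces every file byte for byte.

**Read-mapping depth model.** Depth is generated directly at the level of
per-bin mean read depth (no reads are simulated). The expectations encode
how short reads map to a separately assembled X and Y:

| bin class                    | male    | female                  |
|------------------------------|---------|-------------------------|
| autosomal                    | d       | d                       |
| X/Y outside SDR (shared)     | d/2     | d/2 (reads split X↔Y)   |
| X inside SDR                 | d/2     | d                       |
| Y inside SDR, homologous     | d/2     | 0.05·d (cross-mapping)  |
| Y inside SDR, Y-specific     | d/2     | 0                       |

with d = `mean_depth` (default 30×, a typical resequencing depth).
Outside the SDR the gametologs are effectively identical, so each
individual's reads split evenly between the two contigs; inside the SDR
females' reads map to the less-diverged X copy, leaving only a small
cross-mapping residual (`female_cross_map`, default 0.05) on the Y. This
reproduces the empirical signature the scan relies on: males at half
depth along the whole Y, females near zero across the SDR and at half
depth elsewhere. Consequently mean female raw depth over SDR bins stays
below 1 read/site at default settings.

**Noise law.** Per-bin depth is negative binomial via a gamma–Poisson
mixture with var = μ + α·μ², α = `depth_dispersion` (default 0.1 — mildly
overdispersed relative to Poisson, as real coverage is). α = 0 is the
exact noise-free limit (depth equals its expectation), used by the
perfect-classification tests.

**Geometry.** Defaults: 3 autosomes × 4 Mbp plus a 2 + 2 Mbp sex pair,
SDR at 0.5–1.9 Mbp on the Y, 10 kbp depth bins. The autosome share
(~75 % of bins) matters: the depth normalizer is the genome-wide median,
and if close to half of a male's bins sit at half depth the median is
dragged off the autosomal mode and every ratio inflates toward the band
edges. A desk-scale genome therefore needs a clear autosomal majority;
real genomes (sex pair ≈ 5 % of the assembly) satisfy this easily.

**SDR mosaic.** Each SDR bin is Y-specific with probability
`y_specific_fraction` (default 0.8) else homologous-diverged. Y contig
sequence derives from the X sequence: substitutions at `sdr_divergence`
(default 0.05/site) in diverged bins, `background_divergence` (default 0:
"fully conserved" outside the SDR, matching a young system) elsewhere;
Y-specific bins are replaced outright and excluded from the X–Y alignment
map that the generator also emits.

**SNPs.** Sites arrive at `snp_density` (default 0.006/bp, the order of a
genome-wide SNP rate in a wild fish population). Outside the SDR,
genotypes are Hardy–Weinberg draws at a uniform(0.05, 0.5) allele
frequency, independent of sex. Inside the SDR, homologous-bin sites are
fixed X–Y differences: every male heterozygous, every female homozygous
reference. Y-specific-bin sites are hemizygous: males carry 0 or 2 dosage
(haploid calls), females are missing (`./.`), which the generator asserts
as an invariant. The simulator abstracts straight to genotypes; no
variant-calling toolchain is modelled.

**Gene pair.** `simulate_gene_pair` builds a parent CDS of random sense
codons (7 equal exons by default), drops the truncated exons (1-based
numbers, default {2,3,4} → a 4-exon duplicate), then applies
Poisson(Ks·S) synonymous and Poisson(Ka·N) nonsynonymous single-base
events in random order, each at a uniformly chosen opportunity of the
current sequence, never creating a stop codon. Because events are
weighted by current per-codon opportunity and back-substitutions occur
naturally, NG86 with Jukes–Cantor correction recovers the targets: over
100 replicates at ~10 kb the mean Ks estimate sits within ~1.5 % of the
0.35 target (the acceptance experiment bounds it at 5 %). Single short
genes are noisy — at ~300 codons the Ks standard deviation is ≈ 0.05.

**Repeats.** Intervals with exponential lengths (mean 500 bp) arrive at
class densities LINE 0.05, DNA 0.04, Simple 0.02, LTR 0.01 (the order
observed in percid-like genomes); within `sdg_flank` (default 100 kbp) of
the SDG, extra LINE intervals raise density by `line_enrichment_factor`
(default 3×).

## Linkage classification

Normalized depth = per-contig, length-weighted mean raw depth divided by
the individual's genome-wide **median** per-bin depth (robust to the SDR
itself; "overall genomic depth" is not otherwise defined). Rules, with
`half_depth_low/high` = 0.3/0.7 and `female_absent_max` = 0.1:

* **Y-linked** — male ratio in [0.3, 0.7] and (female ≤ 0.1 **or** marker
  hits > 0). The marker clause matters when X–Y co-mapping gives the Y
  contig an intermediate female ratio.
* **X-linked** — male ratio in [0.3, 0.7], female in (0.1, 1.3], no
  marker hits.
* **autosomal** — both ratios in [0.7, 1.3] (the complement band of the
  half-depth bound around 1).
* **ambiguous** — anything else; contigs are never silently dropped.

Classification is a pure function of (male ratio, female ratio, marker
hits) and is order-independent. Homology of X candidates to Y contigs is
accepted as an optional marker-style input but never computed internally
(no aligner dependency at desk scale).

## Windowed scan and SDR calling

Windows of width w slide by step s (defaults 50/25 kbp, the standard
genome-scan geometry; the desk-scale experiments use 20/10 kbp to match
their 100× smaller chromosomes). The final window truncates at the contig
end.

**Association.** Two-sided Fisher exact test (point-probability method)
on the sex × allele 2×2 table of allele counts; sites with no non-missing
genotype in one sex are excluded and tallied per window as Y-specific
candidates; monomorphic sites get p = 1. No multiple-testing correction
is applied — the window rule consumes the raw −log₁₀P.

**F_ST.** Hudson's two-population estimator per site,
num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
den = p₁(1−p₂) + p₂(1−p₁); windowed as ratio of sums (numerators and
denominators summed separately). Hudson's form was chosen because it is
well behaved for exactly two groups at small n and has a clean
ratio-of-sums window combination. Reported per-site values are clipped to
[0, 1] with the raw value retained.

**Coverage.** Median-normalized depths, overlap-length-weighted within
the window per individual, then averaged per sex.

**d_XY.** p-distance (mismatches / aligned sites) over the intervals of
an X–Y alignment map, per window in Y coordinates; Jukes–Cantor
correction optional and flagged saturated at p ≥ 0.75; windows under
`min_aligned_sites` (default 100) are null.

**SDR rule.** A window qualifies if any of:

1. association: ≥ `min_sig_sites` (default 5) sites with −log₁₀P > 2;
2. coverage: female mean < 0.1 and male mean in [0.3, 0.7];
3. divergence: d_XY > `dxy_min` (default 0, i.e. any divergence when the
   background is fully conserved).

Qualifying windows merge across ≤ `gap_windows` (default 1)
non-qualifying windows; merged intervals need ≥ `min_qualifying_windows`
(default 3) members and are ranked by the summed count of rules fired.
The *count* form of the association rule (rather than the per-window
maximum −log₁₀P) is deliberate: with ~10² SNPs per window and 8 + 8
individuals, the per-window maximum of an exact test fires on a large
fraction of null windows and cannot keep the false-positive rate near
zero, whereas requiring a handful of co-occurring significant sites
preserves full sensitivity inside a real SDR (where essentially every
site is associated) while null windows almost never qualify. The
per-window maximum remains available (`assoc_mode="max"`).

On 20 seeded default simulations the called SDR overlaps truth with
Jaccard ≥ 0.96 in every run (boundary error ≤ 1 step at the start, with
occasional single-window overhangs at the end), and 20 null simulations
produce zero SDR calls. These sizes — 16 Mbp genomes, 20/10 kbp windows,
20 seeds per condition — were chosen so the whole experiment runs in
about two minutes.

## Molecular evolution

**NG86.** Per codon, each position contributes syn-changes/3 synonymous
sites (mutations creating stops count as nonsynonymous opportunity), so
N + S = 3 × codons exactly; site counts are averaged over the two
sequences. Observed differences are averaged over all orderings of
multi-substitution codons, excluding pathways through stop intermediates
(all orderings are used if every pathway is blocked). pN and pS are
Jukes–Cantor corrected; p ≥ 0.75 returns the raw proportion flagged
saturated. Gap codons (whole-codon `---`) and terminal stop pairs are
excluded. NG86 was chosen over ML codon models because it is fully
specifiable and checkable against exhaustive enumeration — the test suite
verifies every sense-codon pair against an independent brute-force
implementation.

**Selection class.** omega = Ka/Ks (undefined at Ks = 0). `positive`
(`purifying`) requires omega > 1 (< 1) *and* a one-sided exact binomial
test of Nd/(Nd+Sd) against the neutral expectation N/(N+S) rejecting at
α = 0.05 (pathway-averaged counts rounded to integers); otherwise
`neutral`. The thresholds are this package's convention — "relaxed
purifying selection" has no single standard test.

**Dating.** T = Ks / (2r) / 10⁶ My. The synonymous rate r is a required
parameter with no default: it is lineage-specific, and the package takes
no position on its value (scripts and examples use r = 3.5×10⁻⁹
subs/site/year purely as an illustrative teleost-order clock; at that
rate Ks = 0.35 gives exactly 50 My).

**Identity.** Percent identity over aligned columns excluding terminal
overhangs, internal gaps counting as mismatches, two decimals. The
built-in global aligner (Biopython PairwiseAligner) uses documented
scores (nucleotide: match 2, mismatch −3, gap open −5, extend −2;
protein: BLOSUM62, −11/−1) and is only used when no alignment is
supplied; tests verify it attains the independent Gotoh DP optimum.

**Indels.** Frameshift iff |len(alt) − len(ref)| mod 3 ≠ 0.

## Repeat enrichment

Densities are merged-masked bp over window bp, per class; merging makes
the computation idempotent, and non-overlapping tilings conserve total
masked bp exactly. Region enrichment (default regions: `sdg_flank` around
the SDG versus the same flank around its autosomal parent) reports the
density fold change, a Fisher exact p on the bp 2×2 table — always
flagged with the caveat that base pairs are autocorrelated, so this p is
anticonservative — and a seeded two-sided block-permutation p (10 kbp
blocks shuffled between regions, ≥ 1000 permutations) that respects the
spatial structure. The flank width is a configurable convention (100 kbp
default); "adjacent region" has no canonical definition.

## Numerical conventions and degenerate inputs

* Coordinates 0-based half-open everywhere in memory; 1-based only in
  VCF/GFF3 serialization.
* Fisher p-values are memoized by table, making 10⁴–10⁵ site scans cheap.
* Windows with no SNPs / no depth bins / too few aligned sites are null
  (NaN), never zero.
* Zero-median individuals, empty regions, invalid window geometry, and
  unknown config keys raise typed errors naming the offender.
* Exact-equality tests of scale invariance use power-of-two factors, the
  only scalars for which floating-point division is exact.

## What the simulations do and do not show

The generator reproduces the *signatures* the pipeline consumes — depth
ratios, hemizygous missingness, fixed X–Y differences, divergence,
LINE excess — under an idealised mapping model with exchangeable
individuals. It does not simulate reads, mapping artefacts, batch or
GC-coverage biases, linkage disequilibrium, population structure,
recombination-gradient boundaries, or annotation errors. Passing the
recovery experiments therefore demonstrates the correctness and
calibration of the statistics and rules under their stated model, not
performance on any particular real dataset; on real data the thresholds
(`female_absent_max`, window sizes, `min_sig_sites`) are the knobs to
revisit first. Absolute genome-scale quantities (assembly sizes,
genome-wide SNP totals, chromosome coordinates of a real SDR, the
identity or dated age of any particular gene pair) depend on real
sequencing data and a chosen clock rate, and are intentionally outside
what desk-scale simulation reproduces.
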