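# sdrscan

Tools for locating a **sex-determining region (SDR)** on a young fish XY
chromosome pair and characterising its candidate **sex-determining gene
(SDG)** — aimed at researchers analysing individual resequencing data from
species with homomorphic sex chromosomes (here modelled on a mandarin-fish
style system with a Y-specific, truncated *amh* duplicate, *amhy*).

The package re-implements the computational core of that analysis as a
tested, reusable pipeline:

* **Linkage classification** — contigs are called autosomal, X-linked or
  Y-linked from per-individual read depth. Each individual's per-contig
  depth is normalized by its genome-wide median; hemizygous (single-copy)
  sequence sits in the half-depth band 0.3–0.7, Y-specific sequence shows
  near-zero female depth, and male-specific marker hits corroborate Y
  calls.
* **Windowed SDR scan** — over sliding windows (50 kbp / 25 kbp step by
  default) the scan computes per-SNP sex association (two-sided Fisher
  exact test on the 2×2 sex × allele table, reported as −log₁₀ *P*),
  Hudson's F_ST (ratio of sums per window), per-sex normalized coverage,
  and X–Y nucleotide distance d_XY (p-distance over an alignment map,
  optional Jukes–Cantor correction). Windows qualify through association
  (≥ `min_sig_sites` SNPs with −log₁₀P > 2), coverage (female < 0.1 and
  male in 0.3–0.7) or divergence (d_XY > 0) rules and are merged into SDR
  intervals.
* **Marker association** — presence/absence of a male-specific marker is
  tested by Fisher's exact test with a perfect-separation flag
  (presence ⇔ male).
* **Duplicate-gene molecular evolution** — Nei–Gojobori (1986) Ka/Ks per
  gene and per exon (pathway-averaged substitution counts, Jukes–Cantor
  corrected), selection-regime classification by an exact binomial test,
  pairwise CDS/protein identity, Ks-based duplication dating
  T = Ks / (2r), and frameshift classification of indels.
* **Repeat windows** — windowed repeat-class densities (masked bp per
  window bp after same-class merging) and LINE enrichment near the SDG
  versus the autosomal parent gene region (Fisher on the bp table plus a
  seeded block-permutation test).
* **Synthetic data** — a seeded generator producing a full XY dataset
  (FASTA, VCF, BED depths, GFF3, repeat track, truth JSON) with known SDR,
  hemizygous depth structure, sex-associated SNPs and an enriched LINE
  neighbourhood, so every stage is testable without any downloads.

## Worked example

Simulate a small XY system (200 kbp sex pair, true SDR at 50–190 kbp) and
run every stage:

```yaml
# demo.yaml
seed: 1
outdir: demo_out
dating_rate: 3.5e-9
simulate:
  n_autosomes: 2
  autosome_length: 400000
  sex_chrom_length: 200000
  sdr_start: 50000
  sdr_end: 190000
  bin_size: 5000
  snp_density: 0.004
scan: {window: 20000, step: 10000}
```

```bash
sdrscan run --config demo.yaml
```

The report (also written to `demo_out/report.json`) contains, among other
numbers:

```
linkage:  chr1 autosomal (M 1.30, F 1.18)   chr2 autosomal (M 1.29, F 1.19)
          chrX X_linked  (M 0.65, F 1.00)   chrY Y_linked  (M 0.63, F 0.19)
sdr_intervals: [[50000, 190000]]   truth: [chrY, 50000, 190000]   jaccard: 1.0
marker:   table [[8, 0], [0, 8]]  p = 1.55e-4  perfect_separation: true
kaks:     ka 0.117  ks 0.244  omega 0.481  class purifying
          cds_identity 86.67  age_my 34.9
enrichment (LINE): fold 2.60  permutation_p 0.003
```

Reading this: both sex contigs show the male half-depth ratio (~0.65);
only chrY also shows female absence and marker hits, so it is the Y. The
called SDR matches the simulated truth exactly (Jaccard 1.0). The marker
is present in all 8 males and no female. The duplicate gene was simulated
at Ks = 0.35; at this demo's short length (285 codons) the NG86 estimate
is noisy (± ~0.05 s.d.), and this seed draws 0.244 — the estimator is
unbiased, as the acceptance experiment at 10 kb shows. With the
illustrative clock r = 3.5×10⁻⁹ subs/site/year the point estimate dates
the duplication at Ks/(2r) ≈ 35 My. LINE density in the SDG flank is 2.6×
the autosomal parent-gene flank (permutation p = 0.003).

Other subcommands: `sdrscan simulate`, `classify`, `scan` (with
`--plots` for Manhattan/coverage figures), `kaks`, `repeats`, `recover`
(multi-seed parameter-recovery experiments), all thin wrappers over the
library API (`import sdrscan`).

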