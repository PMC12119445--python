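"""Synthetic XY-system dataset generator with known ground truth.

The generator emulates a young, largely homomorphic fish XY pair: one X and
one Y contig of equal length assembled separately, with a differentiated
sex-determining region (SDR) on the Y.  Outside the SDR the gametologs are
(nearly) identical, so short reads from either sex map half to each contig
and both sexes show half depth on both.  Inside the SDR the Y is a mosaic of

* Y-specific sequence (no X homolog): male depth ~ mean/2, female ~ 0;
* diverged-but-homologous sequence: male depth ~ mean/2, female depth a
  small residual cross-mapping fraction (females' X reads map to the less
  diverged X copy), with elevated X-Y divergence and fully sex-associated
  SNPs (the Y allele is carried by every male and no female).

The SDR carries a translocated, truncated duplicate of an autosomal gene
(the candidate sex-determining gene), with LINE repeats enriched in its
flanking region.  Per-bin read depth follows a negative-binomial
(gamma-Poisson) law: var = mu + dispersion * mu^2; dispersion 0 is the exact
noise-free limit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigError, ParameterError
from .molev import (
    STOP_CODONS,
    codon_site_fractions,
    translate_codon,
    CodonAlignment,
)

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# Y bin classes
BIN_SHARED = 0       # outside SDR: X and Y effectively identical
BIN_DIVERGED = 1     # inside SDR: homologous but diverged from X
BIN_YSPECIFIC = 2    # inside SDR: no X homolog (hemizygous in males)

REPEAT_CLASSES = ("LINE", "LTR", "DNA", "Simple")
_BG_REPEAT_DENSITY = {"LTR": 0.01, "DNA": 0.04, "Simple": 0.02}
_REPEAT_MEAN_LEN = 500.0


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Per-stage substream: a fixed spawn key offsets each pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_LUT[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class Contig:
    id: str
    length: int
    true_class: str  # autosomal | X_linked | Y_linked


@dataclass(frozen=True)
class Gene:
    id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # absolute, half-open


@dataclass(frozen=True)
class RepeatInterval:
    contig: str
    start: int
    end: int
    cls: str


@dataclass
class GenomeModel:
    """Simulated genome: contigs, annotations and simulation truth."""

    contigs: list[Contig]
    sequences: dict[str, str]
    genes: list[Gene]
    repeats: list[RepeatInterval]
    sdr_truth: tuple[str, int, int] | None
    sdg: str | None
    sdg_parent: str | None
    bin_size: int
    y_bin_class: np.ndarray  # int8 per Y bin
    marker_hits: dict[str, int]
    markers: list[tuple[str, str, int]]  # (id, contig, pos)
    alignment_map: list[tuple[str, int, int, str, int, int, str]]

    @property
    def x_contig(self) -> str:
        return next(c.id for c in self.contigs if c.true_class == "X_linked")

    @property
    def y_contig(self) -> str:
        return next(c.id for c in self.contigs if c.true_class == "Y_linked")

    def contig_length(self, cid: str) -> int:
        return next(c.length for c in self.contigs if c.id == cid)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeModel):
            return NotImplemented
        return (
            self.contigs == other.contigs
            and self.sequences == other.sequences
            and self.genes == other.genes
            and self.repeats == other.repeats
            and self.sdr_truth == other.sdr_truth
            and self.sdg == other.sdg
            and self.sdg_parent == other.sdg_parent
            and self.bin_size == other.bin_size
            and np.array_equal(self.y_bin_class, other.y_bin_class)
            and self.marker_hits == other.marker_hits
            and self.markers == other.markers
            and self.alignment_map == other.alignment_map
        )


@dataclass
class SampleSet:
    """Individuals with sexes, SNP genotypes and binned raw depths.

    Genotypes are coded as ALT allele dosage (0, 1, 2) with -1 for missing
    (females at Y-specific sites).  ``depth`` is raw per-bin mean read depth,
    one column per individual, rows matching ``depth_bins``.
    """

    individuals: list[tuple[str, str]]  # (id, sex M/F)
    variants: pd.DataFrame  # contig, pos, ref, alt, category
    gt: np.ndarray  # int8 (n_sites, n_individuals)
    depth_bins: pd.DataFrame  # contig, start, end
    depth: np.ndarray  # float (n_bins, n_individuals)
    marker_presence: pd.DataFrame  # markers x individuals, bool

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.individuals]

    @property
    def sexes(self) -> np.ndarray:
        return np.array([s for _, s in self.individuals])

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleSet):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True))
            and np.array_equal(self.gt, other.gt)
            and self.depth_bins.reset_index(drop=True).equals(
                other.depth_bins.reset_index(drop=True))
            and np.allclose(self.depth, other.depth)
            and self.marker_presence.equals(other.marker_presence)
        )


@dataclass
class GenePair:
    """A parent CDS and its (possibly truncated) diverged duplicate."""

    parent_cds: str
    duplicate_cds: str
    parent_exons: tuple[tuple[int, int], ...]  # codon ranges in parent
    kept_exons: tuple[int, ...]  # 1-based exon numbers retained
    duplicate_exons: tuple[tuple[int, int], ...]  # codon ranges in duplicate
    true_ks: float
    true_ka: float
    truncation: tuple[int, ...]
    saturated_warning: bool
    seed: int

    @property
    def parent_kept_cds(self) -> str:
        parts = []
        for num in self.kept_exons:
            s, e = self.parent_exons[num - 1]
            parts.append(self.parent_cds[3 * s:3 * e])
        return "".join(parts)

    def alignment(self) -> CodonAlignment:
        """Codon alignment of the duplicate against the kept parent exons."""
        return CodonAlignment(self.parent_kept_cds, self.duplicate_cds,
                              exons=list(self.duplicate_exons))


# --------------------------------------------------------------------------
# genome

def _bin_edges(length: int, bin_size: int) -> np.ndarray:
    edges = np.arange(0, length, bin_size)
    return edges


def _classify_y_bins(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    starts = _bin_edges(cfg.sex_chrom_length, cfg.bin_size)
    ends = np.minimum(starts + cfg.bin_size, cfg.sex_chrom_length)
    mids = (starts + ends) // 2
    cls = np.full(len(starts), BIN_SHARED, dtype=np.int8)
    if cfg.has_sdr:
        in_sdr = (mids >= cfg.sdr_start) & (mids < cfg.sdr_end)
        draw = rng.random(len(starts)) < cfg.y_specific_fraction
        cls[in_sdr & draw] = BIN_YSPECIFIC
        cls[in_sdr & ~draw] = BIN_DIVERGED
    return cls


def _make_gene(gene_id: str, contig: str, start: int, exon_lens: list[int],
               intron_len: int) -> Gene:
    exons = []
    pos = start
    for el in exon_lens:
        exons.append((pos, pos + el))
        pos += el + intron_len
    end = exons[-1][1]
    return Gene(gene_id, contig, start, end, "+", tuple(exons))


def _sample_repeats(contig: str, lo: int, hi: int, cls: str, density: float,
                    rng: np.random.Generator) -> list[RepeatInterval]:
    span = hi - lo
    if span <= 0 or density <= 0:
        return []
    n = rng.poisson(density * span / _REPEAT_MEAN_LEN)
    out = []
    for _ in range(n):
        length = int(rng.exponential(_REPEAT_MEAN_LEN - 50.0)) + 50
        start = lo + int(rng.integers(0, max(span - length, 1)))
        out.append(RepeatInterval(contig, start, min(start + length, hi), cls))
    return out


def simulate_genome(cfg: SimConfig) -> GenomeModel:
    """Build a multi-contig diploid genome model with one XY pair.

    Deterministic given ``cfg.seed``: the X and Y contig sequences share a
    common ancestor, the Y diverging inside the SDR according to
    ``sdr_divergence`` (homologous bins) or being replaced outright
    (Y-specific bins).  The truncated duplicate of the autosomal parent gene
    sits at the centre of the SDR, with LINE repeats enriched by
    ``line_enrichment_factor`` in its flanking window.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 0)

    contigs = [Contig(f"chr{i + 1}", cfg.autosome_length, "autosomal")
               for i in range(cfg.n_autosomes)]
    contigs.append(Contig("chrX", cfg.sex_chrom_length, "X_linked"))
    contigs.append(Contig("chrY", cfg.sex_chrom_length, "Y_linked"))

    sequences: dict[str, str] = {}
    for c in contigs[:-2]:
        sequences[c.id] = _codes_to_str(
            rng.integers(0, 4, c.length, dtype=np.uint8))

    x_codes = rng.integers(0, 4, cfg.sex_chrom_length, dtype=np.uint8)
    sequences["chrX"] = _codes_to_str(x_codes)

    y_bin_class = _classify_y_bins(cfg, rng)
    y_codes = x_codes.copy()
    rate = np.full(cfg.sex_chrom_length, cfg.background_divergence)
    starts = _bin_edges(cfg.sex_chrom_length, cfg.bin_size)
    for b, s in enumerate(starts):
        e = min(s + cfg.bin_size, cfg.sex_chrom_length)
        if y_bin_class[b] == BIN_DIVERGED:
            rate[s:e] = cfg.sdr_divergence
        elif y_bin_class[b] == BIN_YSPECIFIC:
            y_codes[s:e] = rng.integers(0, 4, e - s, dtype=np.uint8)
            rate[s:e] = 0.0
    mut = np.nonzero(rng.random(cfg.sex_chrom_length) < rate)[0]
    y_codes[mut] = (y_codes[mut]
                    + rng.integers(1, 4, len(mut), dtype=np.uint8)) % 4
    sequences["chrY"] = _codes_to_str(y_codes)

    # genes: autosomal parent (7 exons) and its truncated duplicate in the SDR
    genes: list[Gene] = []
    sdg = sdg_parent = None
    parent = _make_gene("amh", "chr1", 100_000, [150] * 7, 100)
    genes.append(parent)
    sdg_parent = parent.id
    if cfg.has_sdr:
        dup_len = 4 * 150 + 3 * 80
        dup_start = max((cfg.sdr_start + cfg.sdr_end) // 2 - dup_len // 2, 0)
        genes.append(_make_gene("amhy", "chrY", dup_start, [150] * 4, 80))
        sdg = "amhy"
    for c in contigs:
        spacing = c.length // (cfg.genes_per_contig + 1)
        for g in range(cfg.genes_per_contig):
            start = spacing * (g + 1) + int(rng.integers(0, 1000))
            genes.append(_make_gene(f"{c.id}_g{g + 1}", c.id, start,
                                    [200] * 3, 150))

    # repeats: background densities per class, LINE enrichment in SDG flank
    repeats: list[RepeatInterval] = []
    for c in contigs:
        repeats.extend(_sample_repeats(c.id, 0, c.length, "LINE",
                                       cfg.line_density, rng))
        for cls, dens in _BG_REPEAT_DENSITY.items():
            repeats.extend(_sample_repeats(c.id, 0, c.length, cls, dens, rng))
    if sdg is not None and cfg.line_enrichment_factor > 1.0:
        g = next(gn for gn in genes if gn.id == sdg)
        lo = max(g.start - cfg.sdg_flank, 0)
        hi = min(g.end + cfg.sdg_flank, cfg.sex_chrom_length)
        extra = cfg.line_density * (cfg.line_enrichment_factor - 1.0)
        repeats.extend(_sample_repeats("chrY", lo, hi, "LINE", extra, rng))

    genes.sort(key=lambda g: (g.contig, g.start, g.id))
    repeats.sort(key=lambda r: (r.contig, r.start, r.end, r.cls))

    markers: list[tuple[str, str, int]] = []
    if cfg.has_sdr and cfg.n_markers:
        pos = np.sort(rng.integers(cfg.sdr_start, cfg.sdr_end, cfg.n_markers))
        markers = [(f"marker{i + 1}", "chrY", int(p))
                   for i, p in enumerate(pos)]
    marker_hits = {c.id: 0 for c in contigs}
    marker_hits["chrY"] = len(markers)

    # X-Y alignment map: every bin with an X homolog, merged into runs
    aln: list[tuple[str, int, int, str, int, int, str]] = []
    run_start = None
    for b, s in enumerate(starts):
        e = min(int(s) + cfg.bin_size, cfg.sex_chrom_length)
        if y_bin_class[b] != BIN_YSPECIFIC:
            if run_start is None:
                run_start = int(s)
            run_end = e
        elif run_start is not None:
            aln.append(("chrX", run_start, run_end, "chrY",
                        run_start, run_end, "+"))
            run_start = None
    if run_start is not None:
        aln.append(("chrX", run_start, run_end, "chrY",
                    run_start, run_end, "+"))

    sdr_truth = (("chrY", cfg.sdr_start, cfg.sdr_end)
                 if cfg.has_sdr else None)
    return GenomeModel(contigs, sequences, genes, repeats, sdr_truth, sdg,
                       sdg_parent, cfg.bin_size, y_bin_class, marker_hits,
                       markers, aln)


# --------------------------------------------------------------------------
# samples

def expected_depth(genome: GenomeModel, cfg: SimConfig
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-bin expected raw depth for (male, female), from the mapping model."""
    rows = []
    exp = []
    d = cfg.mean_depth
    if not cfg.has_sdr:
        sdr_lo, sdr_hi = -1, -1
    else:
        sdr_lo, sdr_hi = cfg.sdr_start, cfg.sdr_end
    for c in genome.contigs:
        starts = _bin_edges(c.length, cfg.bin_size)
        for b, s in enumerate(starts):
            e = min(int(s) + cfg.bin_size, c.length)
            mid = (int(s) + e) // 2
            if c.true_class == "autosomal":
                m = f = d
            elif c.true_class == "X_linked":
                if sdr_lo <= mid < sdr_hi:
                    m, f = d / 2, d
                else:
                    m = f = d / 2
            else:  # Y_linked
                cls = genome.y_bin_class[b]
                if cls == BIN_SHARED:
                    m = f = d / 2
                elif cls == BIN_DIVERGED:
                    m, f = d / 2, cfg.female_cross_map * d
                else:
                    m, f = d / 2, 0.0
            rows.append((c.id, int(s), e))
            exp.append((m, f))
    bins = pd.DataFrame(rows, columns=["contig", "start", "end"])
    return bins, np.asarray(exp, dtype=float)


def simulate_samples(genome: GenomeModel, cfg: SimConfig) -> SampleSet:
    """Draw per-individual depths and genotypes for n males + n females."""
    cfg.validate()
    rng = _rng(cfg.seed, 1)
    individuals = ([(f"M{i + 1}", "M") for i in range(cfg.n_males)]
                   + [(f"F{i + 1}", "F") for i in range(cfg.n_females)])
    sexes = np.array([s for _, s in individuals])
    is_male = sexes == "M"
    n_ind = len(individuals)

    bins, exp_mf = expected_depth(genome, cfg)
    mu = np.where(is_male[None, :], exp_mf[:, [0]], exp_mf[:, [1]])
    if cfg.depth_dispersion == 0:
        depth = mu.astype(float)
    else:
        shape = 1.0 / cfg.depth_dispersion
        lam = rng.gamma(shape, mu * cfg.depth_dispersion)
        depth = rng.poisson(lam).astype(float)

    # SNP sites
    var_rows = []
    gts = []
    if cfg.has_sdr:
        sdr_lo, sdr_hi = cfg.sdr_start, cfg.sdr_end
    else:
        sdr_lo, sdr_hi = -1, -1
    for c in genome.contigs:
        n_sites = rng.poisson(cfg.snp_density * c.length)
        pos = np.unique(rng.integers(0, c.length, min(n_sites, c.length)))
        seq = genome.sequences[c.id]
        for p in pos:
            p = int(p)
            if c.true_class == "Y_linked" and sdr_lo <= p < sdr_hi:
                cls = genome.y_bin_class[p // cfg.bin_size]
                category = ("y_specific" if cls == BIN_YSPECIFIC
                            else "sex_associated")
            else:
                category = "neutral"
            if category == "sex_associated":
                g = np.where(is_male, 1, 0).astype(np.int8)
            elif category == "y_specific":
                maf = rng.uniform(0.05, 0.5)
                g = np.where(is_male,
                             2 * rng.binomial(1, maf, n_ind), -1
                             ).astype(np.int8)
            else:
                maf = rng.uniform(0.05, 0.5)
                g = rng.binomial(2, maf, n_ind).astype(np.int8)
            ref = seq[p]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            var_rows.append((c.id, p, ref, alt, category))
            gts.append(g)
    variants = pd.DataFrame(
        var_rows, columns=["contig", "pos", "ref", "alt", "category"])
    gt = (np.vstack(gts) if gts
          else np.empty((0, n_ind), dtype=np.int8))

    # hemizygosity invariant: no female call at Y-specific sites
    ysp = variants["category"].to_numpy() == "y_specific"
    if ysp.any():
        assert (gt[np.ix_(ysp, ~is_male)] == -1).all(), \
            "hemizygosity violated: female genotype at Y-specific site"

    marker_ids = [m[0] for m in genome.markers]
    presence = pd.DataFrame(
        np.tile(is_male, (len(marker_ids), 1)),
        index=marker_ids, columns=[i for i, _ in individuals])
    return SampleSet(individuals, variants, gt, bins, depth, presence)


# --------------------------------------------------------------------------
# duplicate gene pairs

def _codon_opportunities(codon: str) -> tuple[list[str], list[str]]:
    """Non-stop single-base neighbours of a codon, split syn/nonsyn."""
    aa = translate_codon(codon)
    syn, non = [], []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            (syn if translate_codon(alt) == aa else non).append(alt)
    return syn, non


def simulate_gene_pair(target_ks: float, target_ka: float,
                       truncation: tuple[int, ...] = (), seed: int = 0,
                       n_exons: int = 7, n_codons: int = 500) -> GenePair:
    """Simulate a parent CDS and a truncated, diverged duplicate.

    The duplicate drops the 1-based exons in ``truncation``, then accumulates
    Poisson(target_ks * S) synonymous and Poisson(target_ka * N) nonsynonymous
    single-base events, applied in random order at uniformly chosen
    opportunities of the current sequence (so NG86 with Jukes-Cantor
    correction recovers the targets on average).  Rates above 1 expected
    substitution per site set ``saturated_warning``.
    """
    if target_ks < 0 or target_ka < 0:
        raise ParameterError("substitution rates must be >= 0")
    if n_exons < 1 or n_codons < n_exons:
        raise ParameterError("need n_codons >= n_exons >= 1")
    truncation = tuple(sorted(set(truncation)))
    if truncation and not set(truncation) <= set(range(1, n_exons + 1)):
        raise ParameterError(
            f"truncation must be 1-based exon numbers in 1..{n_exons}")
    if len(truncation) >= n_exons:
        raise ParameterError("cannot truncate every exon")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2,)))

    base = n_codons // n_exons
    lens = [base + (1 if i < n_codons % n_exons else 0)
            for i in range(n_exons)]
    bounds = []
    pos = 0
    for L in lens:
        bounds.append((pos, pos + L))
        pos += L
    parent_codons = [SENSE_CODONS[i]
                     for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    parent_cds = "".join(parent_codons)

    kept = tuple(i for i in range(1, n_exons + 1) if i not in truncation)
    dup_codons: list[str] = []
    dup_bounds = []
    for num in kept:
        s, e = bounds[num - 1]
        dup_bounds.append((len(dup_codons), len(dup_codons) + (e - s)))
        dup_codons.extend(parent_codons[s:e])

    sites = np.array([codon_site_fractions(c) for c in dup_codons])
    S, N = sites[:, 0].sum(), sites[:, 1].sum()
    n_syn = rng.poisson(target_ks * S)
    n_non = rng.poisson(target_ka * N)
    events = np.array([0] * n_syn + [1] * n_non, dtype=np.int8)
    rng.shuffle(events)

    opp = [_codon_opportunities(c) for c in dup_codons]
    counts = np.array([[len(s), len(n)] for s, n in opp], dtype=float)
    for ev in events:
        w = counts[:, ev]
        total = w.sum()
        if total == 0:
            continue
        cum = np.cumsum(w)
        idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
        choices = opp[idx][ev]
        dup_codons[idx] = choices[int(rng.integers(0, len(choices)))]
        opp[idx] = _codon_opportunities(dup_codons[idx])
        counts[idx] = [len(opp[idx][0]), len(opp[idx][1])]

    return GenePair(
        parent_cds="".join(parent_cds),
        duplicate_cds="".join(dup_codons),
        parent_exons=tuple(bounds),
        kept_exons=kept,
        duplicate_exons=tuple(dup_bounds),
        true_ks=float(target_ks),
        true_ka=float(target_ka),
        truncation=truncation,
        saturated_warning=(target_ks > 1.0 or target_ka > 1.0),
        seed=seed,
    )
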