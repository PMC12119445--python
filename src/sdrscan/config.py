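"""Configuration dataclasses for simulation, classification, scanning and dating.

All genomic coordinates are 0-based half-open internally; 1-based coordinates
appear only in VCF/GFF3 serialization.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ConfigError


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass
class SimConfig:
    """Parameters of the synthetic XY-system dataset.

    The default geometry is a desk-scale model of a fish genome with a young,
    largely homomorphic XY pair: a handful of autosomes, one X and one Y
    contig of equal length, and a differentiated sex-determining region (SDR)
    spanning [sdr_start, sdr_end) on the Y.  Setting ``sdr_start == sdr_end``
    produces a null genome without any differentiated region (used for
    false-positive experiments).

    Depth noise follows a negative-binomial (gamma-Poisson) law with
    ``var = mu + depth_dispersion * mu**2``; ``depth_dispersion == 0`` is the
    exact noise-free limit (per-bin depth equals its expectation).
    """

    n_autosomes: int = 3
    autosome_length: int = 4_000_000
    sex_chrom_length: int = 2_000_000
    sdr_start: int = 500_000
    sdr_end: int = 1_900_000
    n_males: int = 8
    n_females: int = 8
    mean_depth: float = 30.0
    depth_dispersion: float = 0.1
    bin_size: int = 10_000
    snp_density: float = 0.006
    sdr_divergence: float = 0.05
    background_divergence: float = 0.0
    y_specific_fraction: float = 0.8
    female_cross_map: float = 0.05
    line_density: float = 0.05
    line_enrichment_factor: float = 3.0
    sdg_flank: int = 100_000
    n_markers: int = 3
    genes_per_contig: int = 5
    seed: int = 0

    def validate(self) -> "SimConfig":
        _require(self.n_autosomes >= 1, "n_autosomes", "must be >= 1")
        _require(self.autosome_length > 0, "autosome_length", "must be > 0")
        _require(self.sex_chrom_length > 0, "sex_chrom_length", "must be > 0")
        _require(
            0 <= self.sdr_start <= self.sdr_end <= self.sex_chrom_length,
            "sdr_start/sdr_end",
            "need 0 <= sdr_start <= sdr_end <= sex_chrom_length "
            "(equal start/end means no SDR)",
        )
        _require(self.n_males >= 1, "n_males", "must be >= 1")
        _require(self.n_females >= 1, "n_females", "must be >= 1")
        _require(self.mean_depth > 0, "mean_depth", "must be > 0")
        _require(self.depth_dispersion >= 0, "depth_dispersion", "must be >= 0")
        _require(self.bin_size > 0, "bin_size", "must be > 0")
        for name in ("snp_density", "sdr_divergence", "background_divergence",
                     "y_specific_fraction", "female_cross_map", "line_density"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must be in [0, 1]")
        _require(self.line_enrichment_factor >= 0,
                 "line_enrichment_factor", "must be >= 0")
        _require(self.sdg_flank >= 0, "sdg_flank", "must be >= 0")
        _require(self.n_markers >= 0, "n_markers", "must be >= 0")
        _require(self.seed >= 0, "seed", "must be >= 0")
        return self

    @property
    def has_sdr(self) -> bool:
        return self.sdr_end > self.sdr_start


@dataclass
class ClassifierConfig:
    """Thresholds for depth-based contig linkage classification.

    ``half_depth_low``/``half_depth_high`` bound the single-copy (hemizygous)
    depth ratio band; ``female_absent_max`` is the maximum female normalized
    depth compatible with Y-specific sequence.  Autosomal calls require both
    sex ratios inside ``[half_depth_high, 2 - half_depth_high]``, i.e. the
    complement band around 1 implied by the half-depth bound.
    """

    half_depth_low: float = 0.3
    half_depth_high: float = 0.7
    female_absent_max: float = 0.1
    min_contig_len: int = 0

    def validate(self) -> "ClassifierConfig":
        _require(0 < self.half_depth_low < self.half_depth_high,
                 "half_depth_low/half_depth_high", "need 0 < low < high")
        _require(self.female_absent_max < self.half_depth_low,
                 "female_absent_max", "must be < half_depth_low")
        _require(self.min_contig_len >= 0, "min_contig_len", "must be >= 0")
        return self

    @property
    def autosome_band(self) -> tuple[float, float]:
        return (self.half_depth_high, 2.0 - self.half_depth_high)


@dataclass
class ScanRules:
    """Window geometry and SDR-calling rules for the windowed scan.

    A window qualifies as SDR evidence when any of the three rules fires:

    * association — the window contains at least ``min_sig_sites`` SNPs with
      -log10(p) above ``neg_log_p_min`` (``assoc_mode="count"``), or its
      per-window maximum -log10(p) exceeds the threshold
      (``assoc_mode="max"``);
    * coverage — mean female normalized coverage below ``female_absent_max``
      while male coverage sits in the hemizygous band;
    * divergence — X-Y divergence (dxy) above ``dxy_min``.

    Qualifying windows are merged with a gap tolerance of ``gap_windows``
    non-qualifying windows, and merged intervals with fewer than
    ``min_qualifying_windows`` qualifying members are discarded.
    """

    window: int = 50_000
    step: int = 25_000
    neg_log_p_min: float = 2.0
    min_sig_sites: int = 5
    assoc_mode: str = "count"
    female_absent_max: float = 0.1
    male_half_low: float = 0.3
    male_half_high: float = 0.7
    dxy_min: float = 0.0
    gap_windows: int = 1
    min_qualifying_windows: int = 3
    min_aligned_sites: int = 100
    jc_correction: bool = False

    def validate(self) -> "ScanRules":
        _require(self.step > 0, "step", "must be > 0")
        _require(self.window >= self.step, "window", "must be >= step")
        _require(self.assoc_mode in ("count", "max"), "assoc_mode",
                 "must be 'count' or 'max'")
        _require(self.min_sig_sites >= 1, "min_sig_sites", "must be >= 1")
        _require(self.gap_windows >= 0, "gap_windows", "must be >= 0")
        _require(self.min_qualifying_windows >= 1,
                 "min_qualifying_windows", "must be >= 1")
        return self


@dataclass
class DatingConfig:
    """Molecular-clock configuration for Ks-based duplication dating.

    ``rate`` is the synonymous substitution rate in substitutions per
    synonymous site per year.  It is lineage-specific and must be supplied by
    the user; no default is assumed.
    """

    rate: float = 0.0

    def validate(self) -> "DatingConfig":
        _require(self.rate > 0, "rate",
                 "synonymous substitution rate must be > 0 (per site per year)")
        return self


def dataclass_from_dict(cls, d: dict, name: str):
    """Build a config dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    return cls(**d).validate()
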