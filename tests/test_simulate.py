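"""Synthetic-data generator: determinism, depth law, hemizygosity, geometry."""
import dataclasses

import numpy as np
import pytest

from sdrscan import SimConfig, simulate_gene_pair, simulate_genome, \
    simulate_samples
from sdrscan.errors import ConfigError, ParameterError
from sdrscan.simulate import BIN_DIVERGED, BIN_SHARED, BIN_YSPECIFIC, \
    expected_depth


def test_invalid_config_names_field():
    with pytest.raises(ConfigError, match="sdr_start"):
        SimConfig(sdr_start=300, sdr_end=100).validate()
    with pytest.raises(ConfigError, match="snp_density"):
        SimConfig(snp_density=2.0).validate()


def test_genome_determinism(small_cfg):
    g1 = simulate_genome(small_cfg)
    g2 = simulate_genome(small_cfg)
    assert g1 == g2


def test_genome_truth_geometry(small_cfg, small_genome):
    g = small_genome
    assert g.sdr_truth == ("chrY", small_cfg.sdr_start, small_cfg.sdr_end)
    classes = [c.true_class for c in g.contigs]
    assert classes.count("X_linked") == 1
    assert classes.count("Y_linked") == 1
    assert g.sdg == "amhy" and g.sdg_parent == "amh"
    sdg = next(gene for gene in g.genes if gene.id == g.sdg)
    assert sdg.contig == "chrY"
    assert small_cfg.sdr_start <= sdg.start < sdg.end <= small_cfg.sdr_end
    assert len(sdg.exons) == 4
    parent = next(gene for gene in g.genes if gene.id == g.sdg_parent)
    assert len(parent.exons) == 7
    # Y bins outside the SDR are shared; inside they are a mosaic
    starts = np.arange(0, small_cfg.sex_chrom_length, small_cfg.bin_size)
    mids = starts + small_cfg.bin_size // 2
    in_sdr = (mids >= small_cfg.sdr_start) & (mids < small_cfg.sdr_end)
    assert (g.y_bin_class[~in_sdr] == BIN_SHARED).all()
    assert set(g.y_bin_class[in_sdr]) <= {BIN_DIVERGED, BIN_YSPECIFIC}


def test_line_enrichment_identity_when_factor_one(small_cfg):
    """With factor 1 the LINE density near the SDG matches background."""
    cfg = dataclasses.replace(small_cfg, line_enrichment_factor=1.0,
                              autosome_length=2_000_000, seed=11)
    g = simulate_genome(cfg)
    sdg = next(gene for gene in g.genes if gene.id == g.sdg)
    lo, hi = sdg.start - cfg.sdg_flank, sdg.end + cfg.sdg_flank
    near = sum(min(r.end, hi) - max(r.start, lo)
               for r in g.repeats
               if r.contig == "chrY" and r.cls == "LINE"
               and r.end > lo and r.start < hi) / (hi - lo)
    bg = sum(r.end - r.start for r in g.repeats
             if r.contig == "chr1" and r.cls == "LINE") / cfg.autosome_length
    assert near == pytest.approx(bg, abs=0.03)  # sampling error at 0.05


def test_noise_free_depth_is_exact(small_cfg, small_genome):
    cfg = dataclasses.replace(small_cfg, depth_dispersion=0.0)
    s = simulate_samples(small_genome, cfg)
    bins, exp = expected_depth(small_genome, cfg)
    is_male = s.sexes == "M"
    assert np.array_equal(s.depth[:, is_male],
                          np.tile(exp[:, [0]], (1, is_male.sum())))
    assert np.array_equal(s.depth[:, ~is_male],
                          np.tile(exp[:, [1]], (1, (~is_male).sum())))
    # male Y-specific bins at exactly half depth
    ymask = (bins["contig"] == "chrY").to_numpy()
    ysp = np.zeros(len(bins), dtype=bool)
    ysp[ymask] = small_genome.y_bin_class == BIN_YSPECIFIC
    assert (s.depth[np.ix_(ysp, is_male)] == cfg.mean_depth / 2).all()


def test_female_depth_near_zero_in_sdr(small_genome, small_cfg):
    """Mean female raw depth over SDR bins stays below 1 read/site."""
    s = simulate_samples(small_genome, small_cfg)
    bins = s.depth_bins
    mid = (bins["start"] + bins["end"]) // 2
    sdr = ((bins["contig"] == "chrY")
           & (mid >= small_cfg.sdr_start)
           & (mid < small_cfg.sdr_end)).to_numpy()
    female = s.sexes == "F"
    assert s.depth[np.ix_(sdr, female)].mean() < 1.0


def test_autosomal_depth_conservation():
    """Genome-wide autosomal mean depth matches the configured mean (2%)."""
    cfg = SimConfig(n_autosomes=1, autosome_length=2_000_000,
                    sex_chrom_length=200_000, sdr_start=50_000,
                    sdr_end=190_000, seed=3)
    g = simulate_genome(cfg)
    s = simulate_samples(g, cfg)
    auto = (s.depth_bins["contig"] == "chr1").to_numpy()
    assert s.depth[auto].mean() == pytest.approx(cfg.mean_depth, rel=0.02)


def test_hemizygosity_and_sex_association(small_samples):
    s = small_samples
    female = s.sexes == "F"
    ysp = (s.variants["category"] == "y_specific").to_numpy()
    assert ysp.any()
    assert (s.gt[np.ix_(ysp, female)] == -1).all()
    assert (s.gt[np.ix_(ysp, ~female)] >= 0).all()
    assoc = (s.variants["category"] == "sex_associated").to_numpy()
    assert (s.gt[np.ix_(assoc, ~female)] == 1).all()
    assert (s.gt[np.ix_(assoc, female)] == 0).all()


def test_samples_determinism(small_genome, small_cfg):
    s1 = simulate_samples(small_genome, small_cfg)
    s2 = simulate_samples(small_genome, small_cfg)
    assert s1 == s2


def test_null_config_has_no_sdr_signal():
    cfg = SimConfig(n_autosomes=1, autosome_length=600_000,
                    sex_chrom_length=200_000, sdr_start=0, sdr_end=0,
                    bin_size=5_000, seed=5)
    g = simulate_genome(cfg)
    assert g.sdr_truth is None and g.sdg is None
    assert (g.y_bin_class == BIN_SHARED).all()
    s = simulate_samples(g, cfg)
    assert (s.variants["category"] == "neutral").all()


# --- gene pairs ------------------------------------------------------------

def test_gene_pair_zero_rates_identical_minus_truncation():
    p = simulate_gene_pair(0.0, 0.0, truncation=(2, 3, 4), seed=1,
                           n_exons=7, n_codons=700)
    assert p.duplicate_cds == p.parent_kept_cds
    assert len(p.duplicate_exons) == 4
    assert p.kept_exons == (1, 5, 6, 7)
    assert len(p.duplicate_cds) == 3 * 400  # 4 of 7 equal exons kept
    assert not p.saturated_warning


def test_gene_pair_truncation_validation():
    with pytest.raises(ParameterError):
        simulate_gene_pair(0.1, 0.1, truncation=(0,))
    with pytest.raises(ParameterError):
        simulate_gene_pair(0.1, 0.1, truncation=(8,), n_exons=7)
    with pytest.raises(ParameterError):
        simulate_gene_pair(-0.1, 0.1)
    assert simulate_gene_pair(1.5, 0.0, seed=0).saturated_warning


def test_gene_pair_determinism():
    a = simulate_gene_pair(0.35, 0.1, (2, 3, 4), seed=9)
    b = simulate_gene_pair(0.35, 0.1, (2, 3, 4), seed=9)
    assert a == b
    c = simulate_gene_pair(0.35, 0.1, (2, 3, 4), seed=10)
    assert c.duplicate_cds != a.duplicate_cds
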