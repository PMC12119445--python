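"""Per-site association, Hudson Fst, windowed statistics and SDR calling."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import fisher_two_sided, hudson_fst_site
from sdrscan import ScanRules, make_windows, snp_sex_association
from sdrscan.errors import InputError
from sdrscan.scan import (call_sdr, fisher_exact_2x2, hudson_components,
                          marker_presence_association,
                          site_association_table, window_coverage,
                          window_dxy, window_fst)

SEXES_8V8 = np.array(["M"] * 8 + ["F"] * 8)
IS_MALE = SEXES_8V8 == "M"


def test_balanced_site_is_null():
    """Same allele counts in both sexes: p = 1, Fst = 0."""
    gt = np.array([1] * 8 + [1] * 8)  # every individual het
    a = snp_sex_association(gt, IS_MALE)
    assert a.p_value == 1.0 and a.neg_log_p == 0.0
    assert a.fst == 0.0 and a.fst_raw < 0  # finite-sample correction


def test_fixed_difference_site():
    """Males all ALT, females all REF: exact tail p and Fst = 1."""
    gt = np.array([2] * 8 + [0] * 8)
    a = snp_sex_association(gt, IS_MALE)
    assert a.fst == 1.0 and a.fst_raw == 1.0
    assert a.p_value == pytest.approx(fisher_two_sided(16, 0, 0, 16),
                                      rel=1e-9)


def test_monomorphic_site_flagged():
    gt = np.zeros(16, dtype=int)
    a = snp_sex_association(gt, IS_MALE)
    assert a.monomorphic and a.p_value == 1.0 and a.fst == 0.0


def test_missing_sex_raises():
    gt = np.array([1] * 8 + [-1] * 8)
    with pytest.raises(InputError):
        snp_sex_association(gt, IS_MALE)


def test_y_specific_sites_skipped_and_tallied(small_samples):
    assoc, skipped = site_association_table(
        small_samples.variants, small_samples.gt, small_samples.sexes,
        contig="chrY")
    n_ysp = (small_samples.variants.query("contig == 'chrY'")["category"]
             == "y_specific").sum()
    assert len(skipped) == n_ysp
    assert len(assoc) + len(skipped) == \
        (small_samples.variants["contig"] == "chrY").sum()


def test_hudson_equals_hand_formula():
    for alt_m, alt_f in [(8, 0), (16, 0), (4, 12), (1, 1), (10, 6)]:
        num, den = hudson_components(alt_m / 16, alt_f / 16, 16, 16)
        if den:
            assert num / den == pytest.approx(
                hudson_fst_site(alt_m, 16, alt_f, 16), rel=1e-12)


def test_window_fst_is_ratio_of_sums():
    """Windowed Fst equals the direct formula on pooled components."""
    rng = np.random.default_rng(2)
    pos = np.sort(rng.choice(50_000, 40, replace=False))
    rows = []
    for p in pos:
        am, af = rng.integers(0, 17, 2)
        if am + af in (0, 32):
            am = 5
        num, den = hudson_components(am / 16, af / 16, 16, 16)
        rows.append(("c", p, num, den))
    assoc = pd.DataFrame(rows, columns=["contig", "pos", "hudson_num",
                                        "hudson_den"])
    wins = make_windows(50_000, 50_000, 25_000, "c")
    got = window_fst(assoc, wins)
    expected = assoc.hudson_num.sum() / assoc.hudson_den.sum()
    assert got[0] == pytest.approx(expected, rel=1e-12)


def test_window_fst_input_order_invariance():
    rng = np.random.default_rng(3)
    pos = rng.choice(100_000, 60, replace=False)
    nums, dens = rng.random(60), rng.random(60) + 0.5
    assoc = pd.DataFrame({"contig": "c", "pos": pos,
                          "hudson_num": nums, "hudson_den": dens})
    wins = make_windows(100_000, 20_000, 10_000, "c")
    shuffled = assoc.sample(frac=1, random_state=1).reset_index(drop=True)
    assert np.allclose(window_fst(assoc, wins), window_fst(shuffled, wins),
                       equal_nan=True)


def test_window_coverage_uniform_and_duplication_invariance():
    bins = pd.DataFrame({"contig": "c",
                         "start": np.arange(10) * 1000,
                         "end": (np.arange(10) + 1) * 1000})
    inds = [("M1", "M"), ("F1", "F")]
    depth = np.full((10, 2), 30.0)
    wins = make_windows(10_000, 5000, 2500, "c")
    cm, cf = window_coverage(bins, depth, inds, wins, "c")
    assert np.allclose(cm, 1.0) and np.allclose(cf, 1.0)
    # duplicating every individual leaves the per-sex means unchanged
    inds2 = inds + [("M2", "M"), ("F2", "F")]
    depth2 = np.hstack([depth, depth])
    cm2, cf2 = window_coverage(bins, depth2, inds2, wins, "c")
    assert np.allclose(cm, cm2) and np.allclose(cf, cf2)


def test_dxy_examples():
    wins = [w for w in make_windows(4, 4, 4, "y")]
    aln = [("x", 0, 4, "y", 0, 4, "+")]
    d, sat = window_dxy("AAAA", "AAAA", aln, wins, min_aligned_sites=1)
    assert d[0] == 0.0
    d, _ = window_dxy("AAAA", "AAAT", aln, wins, min_aligned_sites=1)
    assert d[0] == pytest.approx(0.25)
    d, _ = window_dxy("AAAA", "AAAT", aln, wins, jc=True,
                      min_aligned_sites=1)
    assert d[0] == pytest.approx(-0.75 * math.log(2.0 / 3.0), rel=1e-9)
    assert d[0] == pytest.approx(0.3041, abs=5e-5)


def test_dxy_saturation_flagged():
    wins = make_windows(4, 4, 4, "y")
    aln = [("x", 0, 4, "y", 0, 4, "+")]
    d, sat = window_dxy("AAAA", "TTTT", aln, wins, jc=True,
                        min_aligned_sites=1)
    assert sat[0] and d[0] == 1.0  # raw p returned


def test_dxy_concatenation_conservation():
    """Length-weighted mean of non-overlapping window dxy equals global."""
    rng = np.random.default_rng(4)
    x = "".join(rng.choice(list("ACGT"), 10_000))
    y = list(x)
    mut = rng.choice(10_000, 400, replace=False)
    for m in mut:
        y[m] = "ACGT"[("ACGT".index(y[m]) + 1) % 4]
    y = "".join(y)
    aln = [("x", 0, 10_000, "y", 0, 10_000, "+")]
    wins = make_windows(10_000, 2000, 2000, "y")
    d, _ = window_dxy(x, y, aln, wins, min_aligned_sites=1)
    lengths = np.array([w.length for w in wins])
    global_d, _ = window_dxy(x, y, aln, make_windows(10_000, 10_000,
                                                     10_000, "y"),
                             min_aligned_sites=1)
    assert np.average(d, weights=lengths) == pytest.approx(global_d[0],
                                                           rel=1e-12)


def _stats_frame(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "contig": ["y"] * n,
        "start": np.arange(n) * 10_000,
        "end": (np.arange(n) + 1) * 10_000,
        "n_snps": np.zeros(n, int),
        "n_y_specific": np.zeros(n, int),
        "max_neg_log_p": np.zeros(n),
        "n_sig_sites": np.zeros(n, int),
        "mean_fst": np.zeros(n),
        "cov_m": np.ones(n),
        "cov_f": np.ones(n),
        "dxy": np.zeros(n),
        "dxy_saturated": np.zeros(n, bool),
    }
    base.update(cols)
    return pd.DataFrame(base)


def test_max_logp_rule_qualifies_single_window():
    """A window whose max -log10 p exceeds 2 qualifies under the max rule."""
    stats = _stats_frame(max_neg_log_p=np.array([0.5, 2.5, 0.1]))
    rules = ScanRules(window=10_000, step=10_000, assoc_mode="max",
                      min_qualifying_windows=1, dxy_min=1.0)
    sdr = call_sdr(stats, rules)
    assert sdr.intervals == [(10_000, 20_000)]


def test_all_null_stats_give_empty_call():
    stats = _stats_frame(dxy=np.full(4, np.nan))
    sdr = call_sdr(stats, ScanRules(window=10_000, step=10_000,
                                    dxy_min=1.0))
    assert sdr.empty and sdr.best is None


def test_coverage_and_dxy_rules_merge_with_gap():
    cov_f = np.array([1, 0.02, 0.03, 1, 0.01, 1, 1, 1.0])
    cov_m = np.array([1, 0.5, 0.5, 1, 0.5, 1, 1, 1.0])
    dxy = np.array([0, 0, 0, 0.05, 0, 0, 0, 0.0])
    stats = _stats_frame(cov_f=cov_f, cov_m=cov_m, dxy=dxy)
    rules = ScanRules(window=10_000, step=10_000, gap_windows=1,
                      min_qualifying_windows=3)
    sdr = call_sdr(stats, rules)
    # windows 1,2,3,4 qualify (coverage/coverage/dxy/coverage) -> one run
    assert sdr.intervals == [(10_000, 50_000)]
    flags = sdr.window_flags
    assert flags.loc[3, "dxy_rule"] and not flags.loc[3, "coverage_rule"]


def test_window_stat_snp_order_invariance(small_genome, small_samples):
    from sdrscan.pipeline import scan_candidate
    rules = ScanRules(window=20_000, step=10_000)
    stats1, sdr1, _ = scan_candidate(small_genome, small_samples, rules)
    shuffled = small_samples.variants.sample(frac=1, random_state=0)
    order = shuffled.index.to_numpy()
    import dataclasses
    s2 = dataclasses.replace(
        small_samples, variants=shuffled.reset_index(drop=True),
        gt=small_samples.gt[order])
    stats2, sdr2, _ = scan_candidate(small_genome, s2, rules)
    pd.testing.assert_frame_equal(stats1, stats2)
    assert sdr1.intervals == sdr2.intervals


def test_marker_association_perfect_separation():
    sexes = np.array(["M"] * 8 + ["F"] * 8)
    presence = sexes == "M"
    table, p, perfect = marker_presence_association(presence, sexes)
    assert perfect
    assert table.tolist() == [[8, 0], [0, 8]]
    assert p == pytest.approx(fisher_two_sided(8, 0, 0, 8), rel=1e-9)


def test_marker_association_uninformative():
    sexes = np.array(["M"] * 8 + ["F"] * 8)
    table, p, perfect = marker_presence_association(np.ones(16, bool),
                                                    sexes)
    assert p == 1.0 and not perfect


@given(am=st.integers(0, 16), af=st.integers(0, 16))
def test_fisher_matches_enumeration(am, af):
    p = fisher_exact_2x2(am, 16 - am, af, 16 - af)
    assert p == pytest.approx(fisher_two_sided(am, 16 - am, af, 16 - af),
                              rel=1e-8)


def test_type_one_error_is_controlled():
    """Under a sex-independent null the exact test rejects at most ~alpha."""
    rng = np.random.default_rng(12)
    n_sites, alpha = 10_000, 0.01
    maf = rng.uniform(0.05, 0.5, n_sites)
    gt = rng.binomial(2, maf[:, None], (n_sites, 16))
    rej = 0
    for i in range(n_sites):
        a = snp_sex_association(gt[i], IS_MALE)
        rej += a.p_value <= alpha
    # conservative discrete test: empirical rate below alpha + 3 SE
    assert rej / n_sites <= alpha + 3 * math.sqrt(alpha * (1 - alpha)
                                                  / n_sites)
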