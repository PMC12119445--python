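"""NG86 counting, identity, selection classes, dating, indel framing."""
import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import (SENSE, brute_path_differences, brute_site_fractions,
                      gotoh_score)
from sdrscan import CodonAlignment, DatingConfig, classify_indel, \
    classify_selection, date_duplication, ng86_kaks, pairwise_identity
from sdrscan.errors import ConfigError, InputError
from sdrscan.molev import NUC_SCORES, codon_path_differences, \
    codon_site_fractions, _global_align


def test_identical_sequences_have_zero_rates():
    aln = CodonAlignment("ATGGCTAAA", "ATGGCTAAA")
    r = ng86_kaks(aln)
    assert r.ka == r.ks == 0.0 and r.omega is None
    assert r.N_sites + r.S_sites == pytest.approx(9.0)


def test_single_synonymous_difference():
    """TTT vs TTC is one synonymous difference and nothing else."""
    r = ng86_kaks(CodonAlignment("TTT", "TTC"))
    assert r.Sd == 1.0 and r.Nd == 0.0
    assert r.ks > 0 and r.ka == 0.0


def test_alignment_validation():
    with pytest.raises(InputError):
        CodonAlignment("ATG", "ATGA")
    with pytest.raises(InputError):
        CodonAlignment("AT", "AT")
    with pytest.raises(InputError):
        CodonAlignment("TAAGGG", "ATGGGG")  # internal stop
    with pytest.raises(InputError):
        CodonAlignment("A-GGGG", "ATGGGG")  # partial gap codon
    # whole-codon gap and terminal stop are tolerated
    CodonAlignment("---GGGTAA", "ATGGGGTAA")


def test_gap_codons_excluded_from_counts():
    r = ng86_kaks(CodonAlignment("---GGG", "ATGGGG"))
    assert r.n_codons == 1
    assert r.N_sites + r.S_sites == pytest.approx(3.0)


def test_symmetry_and_site_conservation_on_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 60))
        a = "".join(rng.choice(SENSE, n))
        b = "".join(rng.choice(SENSE, n))
        r1 = ng86_kaks(CodonAlignment(a, b))
        r2 = ng86_kaks(CodonAlignment(b, a))
        assert r1.Sd == pytest.approx(r2.Sd) and r1.Nd == pytest.approx(r2.Nd)
        assert r1.S_sites == pytest.approx(r2.S_sites)
        assert r1.N_sites + r1.S_sites == pytest.approx(3.0 * n)


def test_per_exon_counts_sum_to_gene():
    rng = np.random.default_rng(1)
    n = 30
    a = "".join(rng.choice(SENSE, n))
    b = "".join(rng.choice(SENSE, n))
    exons = [(0, 10), (10, 18), (18, 30)]
    r = ng86_kaks(CodonAlignment(a, b, exons=exons))
    assert sum(e.Nd for e in r.exons) == pytest.approx(r.Nd)
    assert sum(e.Sd for e in r.exons) == pytest.approx(r.Sd)
    assert sum(e.S_sites for e in r.exons) == pytest.approx(r.S_sites)


def test_ng86_matches_bruteforce_on_sample_of_codon_pairs():
    """Spot-check pathway averaging and site counts against enumeration
    (the full sense-codon cross product runs in the acceptance suite)."""
    rng = np.random.default_rng(2)
    for c in rng.choice(SENSE, 40):
        assert codon_site_fractions(c) == pytest.approx(
            brute_site_fractions(c))
    for _ in range(300):
        c1, c2 = rng.choice(SENSE, 2)
        assert codon_path_differences(c1, c2) == pytest.approx(
            brute_path_differences(c1, c2))


def test_selection_classification():
    res = ng86_kaks(CodonAlignment("TTT" * 1, "TTC" * 1))
    assert classify_selection(res) == "neutral"  # one difference: no power
    # strong purifying: many codons, only synonymous changes
    a = "TTT" * 40 + "GGG" * 40
    b = "TTC" * 40 + "GGG" * 40
    assert classify_selection(ng86_kaks(CodonAlignment(a, b))) == "purifying"
    # strong positive: an excess of single nonsynonymous changes over the
    # few synonymous ones (ks > 0 keeps omega defined)
    a = "AAA" * 60 + "TTT" * 10
    b = "GAA" * 60 + "TTC" * 2 + "TTT" * 8
    r = ng86_kaks(CodonAlignment(a, b))
    assert r.omega is not None and r.omega > 1
    assert classify_selection(r) == "positive"
    # ks == 0 -> undefined
    r0 = ng86_kaks(CodonAlignment("ATG", "CTG"))
    assert r0.ks == 0 and classify_selection(r0) == "undefined"


def test_weak_evidence_stays_neutral():
    """omega = 3 from two differences is not significant."""
    r = ng86_kaks(CodonAlignment("ATGATGTTT", "CTGATGTTC"))
    assert r.omega is not None
    assert classify_selection(r) == "neutral"


# --- identity --------------------------------------------------------------

def test_identity_examples():
    assert pairwise_identity("ACGT", "ACGT") == 100.00
    assert pairwise_identity("ACGT", "ACGA") == 75.00
    assert pairwise_identity("MKV", "MKV", level="protein") == 100.00


def test_identity_excludes_terminal_overhangs():
    assert pairwise_identity("ACGT", "ACGTAAAA",
                             alignment=("ACGT----", "ACGTAAAA")) == 100.00
    assert pairwise_identity("x", "x",
                             alignment=("AC-GT", "ACAGT")) == 80.00


def test_aligner_matches_gotoh_dp_oracle():
    """The built-in global aligner attains the brute-force DP optimum."""
    rng = np.random.default_rng(5)
    for _ in range(8):
        a = "".join(rng.choice(list("ACGT"), 200))
        b = list(a)
        for m in rng.choice(200, 20, replace=False):
            b[m] = "ACGT"[("ACGT".index(b[m]) + int(rng.integers(1, 4)))
                          % 4]
        # a couple of short indels
        del b[50:53]
        b[100:100] = list("ACGT"[: int(rng.integers(1, 4))])
        b = "".join(b)
        row_a, row_b = _global_align(a, b, "nucleotide")
        score = 0.0
        in_gap = False
        for ca, cb in zip(row_a, row_b):
            if ca == "-" or cb == "-":
                score += (NUC_SCORES["extend_gap"] if in_gap
                          else NUC_SCORES["open_gap"])
                in_gap = True
            else:
                score += (NUC_SCORES["match"] if ca == cb
                          else NUC_SCORES["mismatch"])
                in_gap = False
        best = gotoh_score(a, b, NUC_SCORES["match"],
                           NUC_SCORES["mismatch"], NUC_SCORES["open_gap"],
                           NUC_SCORES["extend_gap"])
        assert score == pytest.approx(best)


# --- dating and indels -----------------------------------------------------

def test_dating_arithmetic():
    cfg = DatingConfig(rate=3.5e-9)
    assert date_duplication(0.0, cfg) == 0.0
    assert date_duplication(0.35, cfg) == pytest.approx(50.0)
    assert date_duplication((0.30, 0.36), cfg) == \
        pytest.approx((42.857142857, 51.428571428))
    # doubling the rate halves the date
    assert date_duplication(0.35, DatingConfig(rate=7e-9)) == \
        pytest.approx(25.0)
    with pytest.raises(ConfigError):
        date_duplication(0.35, DatingConfig(rate=0.0))


@pytest.mark.parametrize("ref,alt,expected", [
    ("A", "AT", "frameshift"),      # +1 bp
    ("A", "ATTT", "in_frame"),      # +3 bp
    ("ACGT", "AGGT", "in_frame"),   # substitution
    ("ACGTT", "A", "frameshift"),   # -4 bp
])
def test_indel_classification(ref, alt, expected):
    assert classify_indel(ref, alt) == expected


@given(st.text("ACGT", min_size=1, max_size=12),
       st.text("ACGT", min_size=1, max_size=12))
def test_indel_classification_depends_only_on_length_mod3(a, b):
    expected = "frameshift" if abs(len(a) - len(b)) % 3 else "in_frame"
    assert classify_indel(a, b) == expected
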