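"""Duplicate-gene molecular evolution: identity, NG86 Ka/Ks, dating, indels.

Implements the Nei–Gojobori (1986) counting method: per-codon synonymous and
nonsynonymous site fractions averaged over the two sequences, observed
differences averaged over all mutational pathways through multi-substitution
codons, and Jukes–Cantor correction of the raw proportions.  Conventions
(documented because NG86 leaves them open):

* single-base changes that create a stop codon count as nonsynonymous
  opportunities in site counting;
* pathways passing through a stop-codon intermediate are excluded from the
  pathway average; if every pathway is blocked, all pathways are used;
* gap codons (whole-codon ``---``) are excluded from all counts.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import binomtest

from .config import DatingConfig
from .errors import InputError, ParameterError

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
GAP_CODON = "---"

_AA = dict(standard_dna_table.forward_table)
for _c in STOP_CODONS:
    _AA[_c] = "*"


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter, '*' for stop) of an unambiguous DNA codon."""
    return _AA[codon]


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts of one codon.

    Each of the three positions contributes ``syn_changes / 3`` synonymous
    sites; the two counts always sum to exactly 3.
    """
    if codon in STOP_CODONS or "-" in codon:
        raise ParameterError(f"cannot count sites of codon {codon!r}")
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and _AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences c1 -> c2."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if _AA[nxt] == _AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    valid = [(s, n) for b, s, n in paths if not b]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 distance for proportion ``p``; returns (distance, saturated).

    For ``p >= 0.75`` the correction diverges: the raw proportion is returned
    with the saturated flag set.
    """
    if p < 0:
        raise ParameterError("proportion must be >= 0")
    if p >= 0.75:
        return p, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


@dataclass
class CodonAlignment:
    """Two aligned in-frame CDS of equal length (multiple of 3).

    Gaps, if any, must cover whole codons and are excluded from counting.
    ``exons`` optionally partitions the codon index range into half-open
    (start, end) codon ranges.
    """

    seq_a: str
    seq_b: str
    exons: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise InputError("aligned sequences differ in length")
        if len(a) == 0 or len(a) % 3:
            raise InputError("alignment length must be a positive multiple of 3")
        self.seq_a, self.seq_b = a, b
        ncod = len(a) // 3
        for i in range(ncod):
            ca, cb = a[3 * i:3 * i + 3], b[3 * i:3 * i + 3]
            for c in (ca, cb):
                if "-" in c and c != GAP_CODON:
                    raise InputError(f"partial gap codon {c!r} at codon {i}")
                if c in STOP_CODONS and i < ncod - 1:
                    raise InputError(f"internal stop codon {c!r} at codon {i}")
        if self.exons is not None:
            covered = sorted(self.exons)
            flat = [i for s, e in covered for i in (s, e)]
            if flat != sorted(set(flat)) and covered:
                pass  # overlapping ranges caught below
            pos = 0
            for s, e in covered:
                if s != pos or e <= s:
                    raise InputError("exon ranges must partition the codons")
                pos = e
            if pos != ncod:
                raise InputError("exon ranges must partition the codons")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self, codon_range: tuple[int, int] | None = None):
        """Yield (codon_a, codon_b) for comparable (non-gap, non-stop) codons."""
        s, e = codon_range if codon_range else (0, self.n_codons)
        for i in range(s, e):
            ca = self.seq_a[3 * i:3 * i + 3]
            cb = self.seq_b[3 * i:3 * i + 3]
            if GAP_CODON in (ca, cb):
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue  # terminal stop pair: excluded from counts
            yield ca, cb


@dataclass
class KaKsResult:
    """NG86 substitution counts and rates for one gene or exon."""

    label: str
    n_codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float
    ka: float
    omega: float | None
    saturated_s: bool = False
    saturated_n: bool = False
    selection_class: str | None = None
    exons: list["KaKsResult"] | None = None

    @property
    def defined(self) -> bool:
        return self.n_codons > 0


def _count_range(aln: CodonAlignment, rng: tuple[int, int] | None, label: str
                 ) -> KaKsResult:
    S = N = Sd = Nd = 0.0
    n = 0
    for ca, cb in aln.codon_pairs(rng):
        sa, na = codon_site_fractions(ca)
        sb, nb = codon_site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_path_differences(ca, cb)
        Sd += sd
        Nd += nd
        n += 1
    if n == 0:
        return KaKsResult(label, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                          None)
    pS, pN = Sd / S if S else 0.0, Nd / N if N else 0.0
    ks, sat_s = jukes_cantor(pS)
    ka, sat_n = jukes_cantor(pN)
    omega = (ka / ks) if ks > 0 else None
    return KaKsResult(label, n, S, N, Sd, Nd, pS, pN, ks, ka, omega,
                      sat_s, sat_n)


def ng86_kaks(aln: CodonAlignment, label: str = "gene") -> KaKsResult:
    """NG86 Ka/Ks for the whole alignment and (if annotated) per exon."""
    res = _count_range(aln, None, label)
    if aln.exons is not None:
        res.exons = [
            _count_range(aln, (s, e), f"exon{idx + 1}")
            for idx, (s, e) in enumerate(aln.exons)
        ]
    return res


def classify_selection(result: KaKsResult, alpha: float = 0.05) -> str:
    """Selection regime from omega plus an exact binomial test.

    The observed nonsynonymous share Nd / (Nd + Sd) is compared with the
    neutral expectation N / (N + S) by a one-sided exact binomial test
    (pathway-averaged counts rounded to the nearest integer).  ``positive``
    or ``purifying`` require both the omega direction and rejection at
    ``alpha``; anything else is ``neutral``; Ks = 0 (or an empty comparison)
    is ``undefined``.
    """
    if not result.defined or result.ks == 0 or result.omega is None:
        result.selection_class = "undefined"
        return "undefined"
    total = int(round(result.Nd + result.Sd))
    k = int(round(result.Nd))
    k = min(k, total)
    p_neutral = result.N_sites / (result.N_sites + result.S_sites)
    cls = "neutral"
    if result.omega > 1:
        p = binomtest(k, total, p_neutral, alternative="greater").pvalue
        if p < alpha:
            cls = "positive"
    elif result.omega < 1:
        p = binomtest(k, total, p_neutral, alternative="less").pvalue
        if p < alpha:
            cls = "purifying"
    result.selection_class = cls
    return cls


# --- pairwise identity -----------------------------------------------------

#: documented global-alignment scores used when no alignment is supplied
NUC_SCORES = {"match": 2, "mismatch": -3, "open_gap": -5, "extend_gap": -2}
PROT_SCORES = {"matrix": "BLOSUM62", "open_gap": -11, "extend_gap": -1}


def _global_align(a: str, b: str, level: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if level == "nucleotide":
        aligner.match_score = NUC_SCORES["match"]
        aligner.mismatch_score = NUC_SCORES["mismatch"]
        aligner.open_gap_score = NUC_SCORES["open_gap"]
        aligner.extend_gap_score = NUC_SCORES["extend_gap"]
    else:
        aligner.substitution_matrix = substitution_matrices.load(
            PROT_SCORES["matrix"])
        aligner.open_gap_score = PROT_SCORES["open_gap"]
        aligner.extend_gap_score = PROT_SCORES["extend_gap"]
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def identity_from_alignment(row_a: str, row_b: str) -> float:
    """Percent identity over aligned columns, excluding terminal overhangs.

    Internal gap columns count as mismatches; columns inside a leading or
    trailing gap run of either sequence are excluded.
    """
    if len(row_a) != len(row_b) or not row_a:
        raise InputError("alignment rows must be equal-length and non-empty")
    a_res = [i for i, c in enumerate(row_a) if c != "-"]
    b_res = [i for i, c in enumerate(row_b) if c != "-"]
    if not a_res or not b_res:
        raise InputError("alignment has no aligned columns")
    start = max(a_res[0], b_res[0])
    end = min(a_res[-1], b_res[-1]) + 1
    cols = end - start
    if cols <= 0:
        raise InputError("alignment has no aligned columns")
    matches = sum(
        1 for i in range(start, end)
        if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    return round(100.0 * matches / cols, 2)


def pairwise_identity(seq_a: str, seq_b: str, level: str = "nucleotide",
                      alignment: tuple[str, str] | None = None) -> float:
    """Percent identity of two sequences at nucleotide or protein level.

    A pre-computed pairwise alignment (two gapped rows) may be supplied;
    otherwise a global alignment with the documented scores is produced.
    """
    if level not in ("nucleotide", "protein"):
        raise ParameterError("level must be 'nucleotide' or 'protein'")
    if not seq_a or not seq_b:
        raise InputError("sequences must be non-empty")
    if alignment is None:
        alignment = _global_align(seq_a.upper(), seq_b.upper(), level)
    return identity_from_alignment(*alignment)


# --- dating and indels -----------------------------------------------------

def date_duplication(ks, cfg: DatingConfig):
    """Duplication age in million years: T = Ks / (2 r) / 1e6.

    ``ks`` may be a single value or an (low, high) interval; the result has
    the same shape.  ``r`` is the synonymous rate per site per year.
    """
    cfg.validate()
    if isinstance(ks, (tuple, list)):
        return tuple(date_duplication(k, cfg) for k in ks)
    if ks < 0:
        raise ParameterError("ks must be >= 0")
    return ks / (2.0 * cfg.rate) / 1e6


def classify_indel(ref_allele: str, alt_allele: str) -> str:
    """``frameshift`` iff the length difference is not a multiple of 3."""
    if not ref_allele or not alt_allele:
        raise ParameterError("alleles must be non-empty")
    return "frameshift" if abs(len(alt_allele) - len(ref_allele)) % 3 else "in_frame"
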