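"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately written from first principles (hardcoded
genetic code, exact rational hypergeometric enumeration, Gotoh dynamic
programming) and stays independent of the package implementation paths it
checks.
"""
from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

# standard genetic code, TCAG order, '*' = stop
_T = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ORDER = "TCAG"
CODE = {
    a + b + c: _T[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}
SENSE = [c for c, aa in CODE.items() if aa != "*"]


def brute_site_fractions(codon: str) -> tuple[float, float]:
    """(syn, nonsyn) site counts; changes to stops count as nonsynonymous."""
    aa = CODE[codon]
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODE[alt] != "*" and CODE[alt] == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def brute_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences, stop paths excluded."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    all_paths, ok_paths = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, through_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODE[nxt] == "*" and nxt != c2:
                through_stop = True
            if CODE[nxt] == CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not through_stop:
            ok_paths.append((sd, nd))
    paths = ok_paths or all_paths
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Exact rational arithmetic; the point-probability rule sums all tables
    with the observed margins whose probability does not exceed the
    observed one (with the customary 1 + 1e-7 tie tolerance).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = pmf(a)
    cutoff = p_obs + p_obs * Fraction(1, 10_000_000)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum((pmf(k) for k in range(lo, hi + 1) if pmf(k) <= cutoff),
                Fraction(0))
    return float(min(total, Fraction(1)))


def hudson_fst_site(alt1: int, n1: int, alt2: int, n2: int) -> float:
    """Hudson's two-population per-site Fst written out by hand."""
    p1, p2 = alt1 / n1, alt2 / n2
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


def gotoh_score(a: str, b: str, match: float, mismatch: float,
                gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap alignment score (Gotoh DP).

    ``gap_open`` is the score of the first gap position (open+extend
    combined, matching Biopython's open_gap_score convention).
    """
    NEG = float("-inf")
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def masked_bp(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Total covered bp of a set of (possibly overlapping) intervals in
    [lo, hi), by direct per-position marking (small ranges only)."""
    covered = set()
    for s, e in intervals:
        covered.update(range(max(s, lo), min(e, hi)))
    return len(covered)
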