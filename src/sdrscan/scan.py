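"""Windowed sex-association / Fst / coverage / X-Y divergence scan and
rule-based SDR calling.

Per-site association uses a two-sided Fisher exact test on the 2x2 allele
count table (sex x allele); per-site differentiation uses Hudson's Fst
estimator, combined per window as a ratio of sums.  X-Y divergence (dxy) is
a p-distance over an alignment map pairing X and Y coordinates, optionally
Jukes-Cantor corrected.  A window qualifies as SDR evidence through the
association, coverage or divergence rule (see ``ScanRules``); qualifying
windows are merged into maximal intervals with a gap tolerance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .config import ScanRules
from .errors import InputError, ParameterError
from .windows import Window, make_windows

__all__ = [
    "SnpAssoc", "SdrCall", "fisher_exact_2x2", "hudson_components",
    "snp_sex_association", "site_association_table", "window_fst",
    "window_coverage", "window_dxy", "call_sdr",
    "marker_presence_association", "scan_windows",
]


@lru_cache(maxsize=200_000)
def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]] (memoized)."""
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def hudson_components(p1: float, p2: float, n1: int, n2: int
                      ) -> tuple[float, float]:
    """Numerator and denominator of Hudson's two-population Fst estimator.

    ``p1, p2`` are ALT allele frequencies, ``n1, n2`` allele sample sizes.
    Fst_site = num / den; windowed Fst sums components separately.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("Hudson Fst needs >= 2 alleles per group")
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


@dataclass
class SnpAssoc:
    """Association and differentiation summary of one SNP site."""

    contig: str
    pos: int
    alt_m: int
    n_m: int
    alt_f: int
    n_f: int
    p_value: float
    neg_log_p: float
    fst_raw: float  # can be negative or undefined (nan)
    fst: float      # clipped to [0, 1]
    monomorphic: bool


def snp_sex_association(gt: np.ndarray, is_male: np.ndarray,
                        contig: str = "", pos: int = 0) -> SnpAssoc:
    """Fisher exact association and Hudson Fst of one site.

    ``gt`` codes ALT dosage 0/1/2 with -1 missing.  Requires at least one
    non-missing genotype per sex (callers skip and tally sites failing
    this).  Monomorphic sites return p = 1, fst = 0, flagged.
    """
    gt = np.asarray(gt)
    is_male = np.asarray(is_male, dtype=bool)
    gm, gf = gt[is_male], gt[~is_male]
    gm, gf = gm[gm >= 0], gf[gf >= 0]
    if len(gm) == 0 or len(gf) == 0:
        raise InputError("site needs >= 1 non-missing genotype per sex")
    alt_m, n_m = int(gm.sum()), 2 * len(gm)
    alt_f, n_f = int(gf.sum()), 2 * len(gf)
    if (alt_m + alt_f == 0) or (alt_m + alt_f == n_m + n_f):
        return SnpAssoc(contig, pos, alt_m, n_m, alt_f, n_f, 1.0, 0.0,
                        0.0, 0.0, True)
    p = fisher_exact_2x2(alt_m, n_m - alt_m, alt_f, n_f - alt_f)
    num, den = hudson_components(alt_m / n_m, alt_f / n_f, n_m, n_f)
    fst_raw = num / den if den > 0 else math.nan
    fst = min(max(fst_raw, 0.0), 1.0) if math.isfinite(fst_raw) else 0.0
    return SnpAssoc(contig, pos, alt_m, n_m, alt_f, n_f, p,
                    -math.log10(p), fst_raw, fst, False)


def site_association_table(variants: pd.DataFrame, gt: np.ndarray,
                           sexes: np.ndarray, contig: str | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Association table for many sites; returns (assoc, skipped).

    Sites with no non-missing genotype in one sex (e.g. Y-hemizygous sites,
    missing in all females) are excluded from testing and returned in the
    ``skipped`` frame so they can be tallied per window.
    """
    is_male = np.asarray(sexes) == "M"
    mask = np.ones(len(variants), dtype=bool)
    if contig is not None:
        mask &= variants["contig"].to_numpy() == contig
    rows, skipped = [], []
    idx = np.nonzero(mask)[0]
    for i in idx:
        g = gt[i]
        c, p = variants.iloc[i]["contig"], int(variants.iloc[i]["pos"])
        if (g[is_male] >= 0).sum() == 0 or (g[~is_male] >= 0).sum() == 0:
            skipped.append((c, p))
            continue
        a = snp_sex_association(g, is_male, c, p)
        num, den = hudson_components(a.alt_m / a.n_m, a.alt_f / a.n_f,
                                     a.n_m, a.n_f)
        rows.append((a.contig, a.pos, a.p_value, a.neg_log_p,
                     a.fst_raw, a.fst, a.monomorphic, num, den))
    assoc = pd.DataFrame(
        rows, columns=["contig", "pos", "p_value", "neg_log_p",
                       "fst_raw", "fst", "monomorphic",
                       "hudson_num", "hudson_den"])
    skipped_df = pd.DataFrame(skipped, columns=["contig", "pos"])
    return assoc, skipped_df


def _window_index(windows: list[Window], pos: np.ndarray
                  ) -> list[np.ndarray]:
    """Indices of positions falling in each (possibly overlapping) window."""
    pos = np.asarray(pos)
    order = np.argsort(pos, kind="stable")
    ps = pos[order]
    out = []
    for w in windows:
        lo = np.searchsorted(ps, w.start, side="left")
        hi = np.searchsorted(ps, w.end, side="left")
        out.append(order[lo:hi])
    return out


def window_fst(assoc: pd.DataFrame, windows: list[Window]) -> np.ndarray:
    """Hudson ratio-of-sums Fst per window (NaN for empty windows).

    Sums the per-site estimator numerators and denominators (columns
    ``hudson_num`` / ``hudson_den`` of the association table) separately
    within each window before taking the ratio.
    """
    num = assoc["hudson_num"].to_numpy(float)
    den = assoc["hudson_den"].to_numpy(float)
    pos = assoc["pos"].to_numpy()
    out = np.full(len(windows), np.nan)
    for k, idx in enumerate(_window_index(windows, pos)):
        if len(idx) == 0:
            continue
        d = den[idx].sum()
        out[k] = num[idx].sum() / d if d > 0 else np.nan
    return out


def window_coverage(depth_bins: pd.DataFrame, depth: np.ndarray,
                    individuals: list[tuple[str, str]],
                    windows: list[Window], contig: str,
                    medians: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean normalized coverage for (males, females).

    Depth bins are intersected with windows; each individual's bin depths
    are normalized by the individual's genome-wide median, averaged with
    overlap-length weights within the window, then averaged over the
    individuals of each sex.  Windows with no overlapping bin are NaN.
    """
    depth = np.asarray(depth, dtype=float)
    if medians is None:
        medians = np.median(depth, axis=0)
    if (medians <= 0).any():
        raise ParameterError("zero median depth; cannot normalize")
    norm = depth / medians
    sexes = np.array([s for _, s in individuals])
    is_male = sexes == "M"
    mask = depth_bins["contig"].to_numpy() == contig
    starts = depth_bins["start"].to_numpy()[mask]
    ends = depth_bins["end"].to_numpy()[mask]
    nd = norm[mask]
    cov_m = np.full(len(windows), np.nan)
    cov_f = np.full(len(windows), np.nan)
    for k, w in enumerate(windows):
        ov = np.minimum(ends, w.end) - np.maximum(starts, w.start)
        sel = ov > 0
        if not sel.any():
            continue
        wts = ov[sel].astype(float)
        per_ind = (nd[sel] * wts[:, None]).sum(axis=0) / wts.sum()
        cov_m[k] = per_ind[is_male].mean()
        cov_f[k] = per_ind[~is_male].mean()
    return cov_m, cov_f


def window_dxy(x_seq: str, y_seq: str,
               alignment_map: list[tuple[str, int, int, str, int, int, str]],
               windows: list[Window], jc: bool = False,
               min_aligned_sites: int = 100
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window X-Y nucleotide distance over the alignment map.

    Windows are in Y coordinates.  Returns (dxy, saturated_flags); windows
    with fewer than ``min_aligned_sites`` aligned positions are NaN.  With
    ``jc=True`` the Jukes-Cantor correction is applied where p < 0.75;
    saturated windows keep the raw p-distance and are flagged.
    """
    xa = np.frombuffer(x_seq.encode("ascii"), dtype=np.uint8)
    ya = np.frombuffer(y_seq.encode("ascii"), dtype=np.uint8)
    L = len(ya)
    aligned = np.zeros(L, dtype=bool)
    mismatch = np.zeros(L, dtype=bool)
    for xc, xs, xe, yc, ys, ye, strand in alignment_map:
        if strand != "+":
            raise ParameterError("only '+' strand alignment maps supported")
        if (xe - xs) != (ye - ys):
            raise InputError("alignment map interval lengths differ")
        aligned[ys:ye] = True
        mismatch[ys:ye] = xa[xs:xe] != ya[ys:ye]
    ca = np.concatenate([[0], np.cumsum(aligned)])
    cm = np.concatenate([[0], np.cumsum(mismatch)])
    dxy = np.full(len(windows), np.nan)
    saturated = np.zeros(len(windows), dtype=bool)
    for k, w in enumerate(windows):
        n = ca[w.end] - ca[w.start]
        if n < min_aligned_sites:
            continue
        p = (cm[w.end] - cm[w.start]) / n
        if jc:
            if p >= 0.75:
                dxy[k] = p
                saturated[k] = True
            else:
                dxy[k] = -0.75 * math.log1p(-4.0 * p / 3.0)
        else:
            dxy[k] = p
    return dxy, saturated


def scan_windows(contig: str, contig_length: int, rules: ScanRules,
                 assoc: pd.DataFrame, skipped: pd.DataFrame,
                 depth_bins: pd.DataFrame, depth: np.ndarray,
                 individuals: list[tuple[str, str]],
                 x_seq: str | None = None, y_seq: str | None = None,
                 alignment_map=None) -> pd.DataFrame:
    """Assemble the per-window statistics table for one candidate contig."""
    rules.validate()
    windows = make_windows(contig_length, rules.window, rules.step, contig)
    pos = assoc["pos"].to_numpy()
    nlp = assoc["neg_log_p"].to_numpy(float)
    idxs = _window_index(windows, pos)
    max_nlp = np.array([nlp[i].max() if len(i) else 0.0 for i in idxs])
    n_sig = np.array([(nlp[i] > rules.neg_log_p_min).sum() for i in idxs])
    n_snps = np.array([len(i) for i in idxs])
    sk_idx = _window_index(windows, skipped["pos"].to_numpy())
    n_ysp = np.array([len(i) for i in sk_idx])
    fst = window_fst(assoc, windows)
    cov_m, cov_f = window_coverage(depth_bins, depth, individuals, windows,
                                   contig)
    if x_seq is not None and y_seq is not None and alignment_map is not None:
        dxy, sat = window_dxy(x_seq, y_seq, alignment_map, windows,
                              jc=rules.jc_correction,
                              min_aligned_sites=rules.min_aligned_sites)
    else:
        dxy = np.full(len(windows), np.nan)
        sat = np.zeros(len(windows), dtype=bool)
    return pd.DataFrame({
        "contig": contig,
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "n_snps": n_snps,
        "n_y_specific": n_ysp,
        "max_neg_log_p": max_nlp,
        "n_sig_sites": n_sig,
        "mean_fst": fst,
        "cov_m": cov_m,
        "cov_f": cov_f,
        "dxy": dxy,
        "dxy_saturated": sat,
    })


@dataclass
class SdrCall:
    """Merged qualifying intervals with per-window rule flags."""

    contig: str
    intervals: list[tuple[int, int]]
    scores: list[float]
    window_flags: pd.DataFrame
    n_qualifying: int

    @property
    def empty(self) -> bool:
        return not self.intervals

    @property
    def best(self) -> tuple[int, int] | None:
        if self.empty:
            return None
        return self.intervals[int(np.argmax(self.scores))]


def call_sdr(stats: pd.DataFrame, rules: ScanRules | None = None) -> SdrCall:
    """Apply the qualification rules and merge windows into SDR intervals.

    A window qualifies through the association rule (count of sites with
    -log10 p above the threshold, or the per-window maximum, depending on
    ``assoc_mode``), the coverage rule (female coverage below the absence
    threshold with male coverage in the hemizygous band) or the divergence
    rule (dxy above ``dxy_min``).  Qualifying windows at most
    ``gap_windows`` apart merge; merged intervals need at least
    ``min_qualifying_windows`` qualifying members.  Intervals are ranked by
    the summed number of rules fired.
    """
    rules = (rules or ScanRules()).validate()
    if len(stats) == 0:
        raise InputError("empty window table")
    contig = str(stats["contig"].iloc[0])
    if rules.assoc_mode == "count":
        assoc_q = stats["n_sig_sites"].to_numpy() >= rules.min_sig_sites
    else:
        assoc_q = stats["max_neg_log_p"].to_numpy() > rules.neg_log_p_min
    cov_m = stats["cov_m"].to_numpy(float)
    cov_f = stats["cov_f"].to_numpy(float)
    cov_q = (np.nan_to_num(cov_f, nan=np.inf) < rules.female_absent_max) \
        & (cov_m >= rules.male_half_low) & (cov_m <= rules.male_half_high)
    dxy = stats["dxy"].to_numpy(float)
    dxy_q = np.nan_to_num(dxy, nan=-1.0) > rules.dxy_min
    qualifies = assoc_q | cov_q | dxy_q
    score = assoc_q.astype(int) + cov_q.astype(int) + dxy_q.astype(int)

    flags = stats[["contig", "start", "end"]].copy()
    flags["assoc_rule"] = assoc_q
    flags["coverage_rule"] = cov_q
    flags["dxy_rule"] = dxy_q
    flags["qualifies"] = qualifies

    q_idx = np.nonzero(qualifies)[0]
    intervals: list[tuple[int, int]] = []
    scores: list[float] = []
    if len(q_idx):
        groups = [[q_idx[0]]]
        for i in q_idx[1:]:
            if i - groups[-1][-1] <= rules.gap_windows + 1:
                groups[-1].append(i)
            else:
                groups.append([i])
        for g in groups:
            if len(g) < rules.min_qualifying_windows:
                continue
            start = int(stats["start"].iloc[g[0]])
            end = int(stats["end"].iloc[g[-1]])
            intervals.append((start, end))
            scores.append(float(score[g].sum()))
    order = np.argsort(scores)[::-1]
    intervals = [intervals[i] for i in order]
    scores = [scores[i] for i in order]
    return SdrCall(contig, intervals, scores, flags, int(qualifies.sum()))


def marker_presence_association(presence: np.ndarray, sexes: np.ndarray
                                ) -> tuple[np.ndarray, float, bool]:
    """Sex x presence 2x2 table, Fisher exact p and perfect-separation flag.

    ``perfect_separation`` is True iff presence holds for every male and no
    female (presence <=> male).
    """
    presence = np.asarray(presence, dtype=bool)
    is_male = np.asarray(sexes) == "M"
    if is_male.all() or (~is_male).all():
        raise InputError("need at least one individual per sex")
    a = int((presence & is_male).sum())
    b = int((~presence & is_male).sum())
    c = int((presence & ~is_male).sum())
    d = int((~presence & ~is_male).sum())
    table = np.array([[a, b], [c, d]])
    p = fisher_exact_2x2(a, b, c, d)
    perfect = bool((presence == is_male).all())
    return table, p, perfect
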