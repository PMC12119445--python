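"""Windowed repeat-class density and region enrichment statistics.

Densities are masked bp per window bp after merging overlapping intervals
of the same class.  Region enrichment reports the density fold change, a
Fisher exact p on the masked/unmasked bp table (with an autocorrelation
caveat: base pairs are not independent observations) and a seeded block
permutation p that respects the spatial structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .windows import Window
from .scan import fisher_exact_2x2

REPEAT_CLASSES = ("LINE", "LTR", "DNA", "Simple", "other")


def merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _overlap(merged: list[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in merged)


@dataclass
class RepeatTrack:
    """Repeat annotation intervals with a class label per interval."""

    frame: pd.DataFrame  # contig, start, end, cls

    def __post_init__(self) -> None:
        req = {"contig", "start", "end", "cls"}
        if not req <= set(self.frame.columns):
            raise InputError(f"repeat track needs columns {sorted(req)}")

    def classes(self) -> list[str]:
        return sorted(self.frame["cls"].unique())

    def merged(self, contig: str, cls: str) -> list[tuple[int, int]]:
        f = self.frame
        sel = f[(f["contig"] == contig) & (f["cls"] == cls)]
        return merge_intervals(list(zip(sel["start"].astype(int),
                                        sel["end"].astype(int))))


def repeat_density(track: RepeatTrack, windows: list[Window],
                   contig: str) -> pd.DataFrame:
    """Per-window, per-class density = merged masked bp / window bp.

    Classes are merged independently, so the per-window class densities can
    sum above 1 only when annotations of different classes overlap; such
    windows are flagged in ``class_overlap``.
    """
    cols = {"contig": contig,
            "start": [w.start for w in windows],
            "end": [w.end for w in windows]}
    total = np.zeros(len(windows))
    for cls in track.classes():
        merged = track.merged(contig, cls)
        dens = np.array([
            _overlap(merged, w.start, w.end) / w.length for w in windows])
        cols[cls] = dens
        total += dens
    out = pd.DataFrame(cols)
    out["class_overlap"] = total > 1.0 + 1e-12
    return out


@dataclass
class EnrichmentResult:
    """Repeat-class enrichment of region A relative to region B."""

    cls: str
    masked_a: int
    total_a: int
    masked_b: int
    total_b: int
    fold: float
    fisher_p: float
    fisher_caveat: bool  # bp are autocorrelated; exact p is anticonservative
    permutation_p: float
    n_permutations: int

    @property
    def density_a(self) -> float:
        return self.masked_a / self.total_a

    @property
    def density_b(self) -> float:
        return self.masked_b / self.total_b


def _region_blocks(regions: list[tuple[str, int, int]], block: int
                   ) -> list[tuple[str, int, int]]:
    out = []
    for contig, lo, hi in regions:
        for s in range(lo, hi, block):
            out.append((contig, s, min(s + block, hi)))
    return out


def region_enrichment(track: RepeatTrack,
                      region_a: list[tuple[str, int, int]],
                      region_b: list[tuple[str, int, int]],
                      cls: str,
                      n_permutations: int = 1000,
                      block: int = 10_000,
                      seed: int = 0) -> EnrichmentResult:
    """Density fold change of ``cls`` in region A vs B with two p-values.

    Regions are lists of (contig, start, end) intervals and must be
    non-empty and disjoint.  The Fisher p treats each bp as independent
    (flagged as a caveat); the permutation p shuffles ``block``-sized tiles
    between the two regions ``n_permutations`` times with the given seed
    and is two-sided on the density difference.
    """
    for name, region in (("region_a", region_a), ("region_b", region_b)):
        if not region or any(e <= s for _, s, e in region):
            raise ParameterError(f"{name} must be non-empty with positive "
                                 "length intervals")
    merged = {c: track.merged(c, cls)
              for c in {r[0] for r in region_a + region_b}}

    def masked_total(region):
        m = sum(_overlap(merged[c], s, e) for c, s, e in region)
        t = sum(e - s for c, s, e in region)
        return m, t

    ma, ta = masked_total(region_a)
    mb, tb = masked_total(region_b)
    da, db = ma / ta, mb / tb
    fold = float("inf") if db == 0 and da > 0 else (
        1.0 if db == 0 else da / db)
    fisher_p = fisher_exact_2x2(ma, ta - ma, mb, tb - mb)

    blocks_a = _region_blocks(region_a, block)
    blocks_b = _region_blocks(region_b, block)
    blocks = blocks_a + blocks_b
    bm = np.array([_overlap(merged[c], s, e) for c, s, e in blocks],
                  dtype=float)
    bt = np.array([e - s for _, s, e in blocks], dtype=float)
    na = len(blocks_a)
    obs = abs(da - db)
    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(len(blocks))
    for _ in range(n_permutations):
        rng.shuffle(idx)
        pa = idx[:na]
        pb = idx[na:]
        diff = abs(bm[pa].sum() / bt[pa].sum()
                   - bm[pb].sum() / bt[pb].sum())
        if diff >= obs - 1e-15:
            hits += 1
    perm_p = (hits + 1) / (n_permutations + 1)
    return EnrichmentResult(cls, ma, ta, mb, tb, fold, fisher_p, True,
                            perm_p, n_permutations)


def read_repeatmasker_out(path) -> RepeatTrack:
    """Parse a RepeatMasker ``.out`` file into a RepeatTrack.

    Whitespace-delimited dialect with the standard 3-line header; the class
    is the repeat class/family column's prefix before '/'.  Coordinates are
    converted from 1-based inclusive to 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header or blank
            contig, start, end = parts[4], int(parts[5]) - 1, int(parts[6])
            fam = parts[10]
            cls = fam.split("/")[0].rstrip("?")
            if cls not in REPEAT_CLASSES:
                cls = "other"
            rows.append((contig, start, end, cls))
    return RepeatTrack(pd.DataFrame(
        rows, columns=["contig", "start", "end", "cls"]))
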