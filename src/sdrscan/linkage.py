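"""Depth-based contig linkage classification (autosomal / X / Y).

Normalized depth is each individual's per-contig mean raw depth divided by
that individual's genome-wide median per-bin depth, making classification
invariant to sequencing effort.  The decision rules follow the half-depth
band logic used for assembly-time sex-chromosome identification:

* Y-linked: male ratio in the hemizygous band [low, high] and either the
  female ratio is compatible with absence (<= female_absent_max) or the
  contig carries male-specific marker hits;
* X-linked: male ratio in the hemizygous band, female ratio above the
  absence threshold but at most 2 - high, and no marker hits;
* autosomal: both sex ratios inside [high, 2 - high] (the band around 1);
* anything else: ambiguous (never silently dropped).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ClassifierConfig
from .errors import NormalizationError

CLASSES = ("autosomal", "X_linked", "Y_linked", "ambiguous")


@dataclass
class DepthProfile:
    """Per-contig normalized depth per individual, with sex labels."""

    ratios: pd.DataFrame  # index: contig, columns: individual ids
    sexes: dict[str, str]  # individual id -> "M"/"F"

    def sex_mean(self, contig: str) -> tuple[float, float]:
        row = self.ratios.loc[contig]
        males = [i for i, s in self.sexes.items() if s == "M"]
        females = [i for i, s in self.sexes.items() if s == "F"]
        return float(row[males].mean()), float(row[females].mean())


@dataclass(frozen=True)
class LinkageCall:
    contig: str
    linkage: str
    male_ratio: float
    female_ratio: float
    marker_hits: int


def normalize_depth(depth_bins: pd.DataFrame, depth: np.ndarray,
                    individuals: list[tuple[str, str]]) -> DepthProfile:
    """Normalize raw per-bin depths by each individual's genome-wide median.

    Scaling one individual's raw depths by any constant c > 0 leaves the
    profile unchanged.  Raises if any individual's median depth is zero.
    """
    ids = [i for i, _ in individuals]
    sexes = {i: s for i, s in individuals}
    depth = np.asarray(depth, dtype=float)
    medians = np.median(depth, axis=0)
    for ind, med in zip(ids, medians):
        if med <= 0:
            raise NormalizationError(
                f"individual {ind!r} has zero median depth")
    lengths = (depth_bins["end"] - depth_bins["start"]).to_numpy(float)
    contigs = depth_bins["contig"].to_numpy()
    rows = {}
    for contig in pd.unique(contigs):
        mask = contigs == contig
        w = lengths[mask]
        contig_mean = (depth[mask] * w[:, None]).sum(axis=0) / w.sum()
        rows[contig] = contig_mean / medians
    ratios = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    ratios.index.name = "contig"
    return DepthProfile(ratios, sexes)


def classify_one(male_ratio: float, female_ratio: float, marker_hits: int,
                 cfg: ClassifierConfig) -> str:
    """Pure decision rule on the evidence triple."""
    lo, hi = cfg.half_depth_low, cfg.half_depth_high
    a_lo, a_hi = cfg.autosome_band
    male_half = lo <= male_ratio <= hi
    if male_half and (female_ratio <= cfg.female_absent_max
                      or marker_hits > 0):
        return "Y_linked"
    if (male_half and cfg.female_absent_max < female_ratio <= a_hi
            and marker_hits == 0):
        return "X_linked"
    if a_lo <= male_ratio <= a_hi and a_lo <= female_ratio <= a_hi:
        return "autosomal"
    return "ambiguous"


def classify_contigs(profile: DepthProfile,
                     marker_hits: dict[str, int] | None = None,
                     cfg: ClassifierConfig | None = None,
                     contig_lengths: dict[str, int] | None = None
                     ) -> list[LinkageCall]:
    """Classify every contig in the profile; order-independent and pure.

    ``marker_hits`` maps contig id to the number of male-specific marker
    sequences located on it (0 when absent).  Contigs shorter than
    ``cfg.min_contig_len`` (when lengths are supplied) are skipped.
    """
    cfg = (cfg or ClassifierConfig()).validate()
    marker_hits = marker_hits or {}
    calls = []
    for contig in profile.ratios.index:
        if (contig_lengths is not None
                and contig_lengths.get(contig, cfg.min_contig_len)
                < cfg.min_contig_len):
            continue
        m, f = profile.sex_mean(contig)
        hits = int(marker_hits.get(contig, 0))
        calls.append(LinkageCall(contig, classify_one(m, f, hits, cfg),
                                 m, f, hits))
    return calls


def calls_to_frame(calls: list[LinkageCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.contig, c.linkage, c.male_ratio, c.female_ratio, c.marker_hits)
         for c in calls],
        columns=["contig", "class", "male_ratio", "female_ratio", "markers"])
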