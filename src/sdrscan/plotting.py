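"""Minimal static figures: Manhattan plot and per-sex coverage track."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_manhattan(assoc: pd.DataFrame, path, threshold: float = 2.0) -> None:
    """-log10(p) (top) and per-site Fst (bottom) along the contig."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
    x = assoc["pos"] / 1e6
    ax1.scatter(x, assoc["neg_log_p"], s=4, c="steelblue")
    ax1.axhline(threshold, color="crimson", ls="--", lw=1)
    ax1.set_ylabel(r"$-\log_{10} P$")
    ax2.scatter(x, assoc["fst"], s=4, c="darkorange")
    ax2.set_ylabel(r"$F_{ST}$")
    ax2.set_xlabel("position (Mbp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coverage(stats: pd.DataFrame, path) -> None:
    """Windowed male/female normalized coverage with the dxy track."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
    x = (stats["start"] + stats["end"]) / 2 / 1e6
    ax1.plot(x, stats["cov_m"], label="males", c="steelblue")
    ax1.plot(x, stats["cov_f"], label="females", c="crimson")
    ax1.set_ylabel("normalized coverage")
    ax1.legend(frameon=False)
    ax2.plot(x, stats["dxy"], c="darkgreen")
    ax2.set_ylabel(r"$d_{XY}$")
    ax2.set_xlabel("position (Mbp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
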