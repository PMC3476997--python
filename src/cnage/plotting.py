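"""Schematic figures: genome-wide alteration frequencies, per-chromosome
correlation/frequency detail, and the correlation-coefficient density.

Every plotting function writes an image and returns the plotted arrays so
tests can assert on the data rather than on pixels.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .correlation import LocusCorrelation
from .tracks import FeatureTrack


def _genome_positions(track: FeatureTrack) -> np.ndarray:
    """Cumulative genome coordinate of each locus midpoint."""
    offsets: dict[str, int] = {}
    running = 0
    for chrom, sl in track.chrom_slices().items():
        offsets[chrom] = running
        running += int(track.ends[sl.stop - 1]) + 1
    return np.array(
        [offsets[c] + m for c, m in zip(track.chroms, track.midpoints)], dtype=float
    )


def plot_genome_frequency(
    counts: pd.DataFrame,
    track: FeatureTrack,
    n_samples: int,
    path: str,
    marker_frequency: float | None = 0.25,
) -> dict:
    """Genome-wide GE up/down (dark) and CN gain/loss (light) frequencies.

    Losses/down-regulation are drawn downward; an optional horizontal marker
    highlights the given recurrence level.
    """
    loci = [l for l in track.ids if l in counts.index]
    fig, ax = plt.subplots(figsize=(10, 3))
    data = {
        "position": np.array([]),
        "ge_up": np.array([]),
        "ge_down": np.array([]),
        "cn_gain": np.array([]),
        "cn_loss": np.array([]),
    }
    if loci:
        sub = counts.loc[loci]
        keep = np.isin(track.ids, loci)
        pos = _genome_positions(track)[keep]
        ge_up = sub[["U-G", "U-N", "U-L"]].sum(axis=1).to_numpy() / n_samples
        ge_down = sub[["D-G", "D-N", "D-L"]].sum(axis=1).to_numpy() / n_samples
        cn_gain = sub[["U-G", "N-G", "D-G"]].sum(axis=1).to_numpy() / n_samples
        cn_loss = sub[["U-L", "N-L", "D-L"]].sum(axis=1).to_numpy() / n_samples
        ax.fill_between(pos, 0, cn_gain, color="#f5b8b1", label="CN gain")
        ax.fill_between(pos, 0, -cn_loss, color="#c3e6c3", label="CN loss")
        ax.fill_between(pos, 0, ge_up, color="#c0392b", alpha=0.7, label="GE up")
        ax.fill_between(pos, 0, -ge_down, color="#1e8449", alpha=0.7, label="GE down")
        if marker_frequency is not None:
            ax.axhline(marker_frequency, color="blue", lw=0.8)
            ax.axhline(-marker_frequency, color="blue", lw=0.8)
        data = {
            "position": pos,
            "ge_up": ge_up,
            "ge_down": ge_down,
            "cn_gain": cn_gain,
            "cn_loss": cn_loss,
        }
    ax.set_xlabel("genome position")
    ax.set_ylabel("alteration frequency")
    ax.set_ylim(-1.05, 1.05)
    if len(loci):
        ax.legend(loc="upper right", fontsize=6, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return data


def plot_chromosome_detail(
    correlations: list[LocusCorrelation],
    counts: pd.DataFrame,
    track: FeatureTrack,
    chrom: str,
    n_samples: int,
    path: str,
    r_threshold: float = 0.60,
) -> dict:
    """One chromosome: correlation dots (colored by significance) over the
    U-G (or D-L) category frequency profile."""
    by_locus = {c.locus: c for c in correlations}
    rows = [
        k
        for k in range(len(track))
        if track.chroms[k] == chrom and str(track.ids[k]) in by_locus
    ]
    mids = track.midpoints[rows].astype(float)
    r = np.array([by_locus[str(track.ids[k])].r for k in rows])
    significant = np.array(
        [by_locus[str(track.ids[k])].significant for k in rows], dtype=bool
    )
    ids = [str(track.ids[k]) for k in rows]
    present = [i for i in ids if i in counts.index]
    ug_freq = (
        counts.loc[present, "U-G"].to_numpy(dtype=float) / n_samples
        if present
        else np.array([])
    )
    fig, ax = plt.subplots(figsize=(8, 3))
    if len(present):
        keep = np.isin(ids, present)
        ax.fill_between(mids[keep], 0, ug_freq, color="#f8c8dc", label="U-G frequency")
    if len(rows):
        ax.scatter(mids[~significant], r[~significant], s=8, color="#2e63a4", label="r")
        ax.scatter(
            mids[significant],
            r[significant],
            s=8,
            color="#7d3c98",
            label=f"r >= {r_threshold:.2f}",
        )
    ax.set_xlabel(f"{chrom} position (bp)")
    ax.set_ylabel("Pearson r / frequency")
    ax.set_ylim(-1.05, 1.05)
    ax.legend(loc="lower right", fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return {
        "midpoint": mids,
        "r": r,
        "significant": significant,
        "ug_frequency": ug_freq,
    }


def plot_correlation_density(
    correlations: list[LocusCorrelation], path: str, r_threshold: float = 0.60
) -> dict:
    """Density of per-locus r with the significant (r >= threshold) mass shaded."""
    r = np.array([c.r for c in correlations if not np.isnan(c.r)])
    fig, ax = plt.subplots(figsize=(5, 3.2))
    highlighted_fraction = 0.0
    if r.size:
        grid = np.linspace(-1.05, 1.05, 256)
        if r.size > 1 and np.std(r) > 0:
            from scipy.stats import gaussian_kde

            density = gaussian_kde(r)(grid)
        else:
            density = np.zeros_like(grid)
        ax.plot(grid, density, color="#2e63a4")
        ax.fill_between(
            grid, 0, density, where=grid >= r_threshold, color="#7d3c98", alpha=0.6
        )
        highlighted_fraction = float(np.mean(r >= r_threshold))
        ax.axvline(r_threshold, color="black", lw=0.8, ls="--")
    ax.set_xlabel("Pearson r (GE vs CN)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return {"r": r, "highlighted_fraction": highlighted_fraction}
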