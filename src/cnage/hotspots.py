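"""Hotspot-region calling: intersect correlation and frequency evidence.

A gene locus qualifies for a direction (U-G or D-L) when it is
correlation-significant (r >= threshold, or rescued by outlier recovery) AND
its sample count in that joint category reaches the direction's frequency
cutoff.  Consecutive qualifying loci merge into a region, tolerating up to
``max_gap_loci`` non-qualifying loci between them; regions never cross
chromosomes.  Region summaries average the member loci's correlation
coefficients and their category frequency (as percent of samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import LocusCorrelation
from .discretize import FrequencyCutoffs
from .tracks import FeatureTrack

UG = "UG"
DL = "DL"
_CATEGORY = {UG: "U-G", DL: "D-L"}


@dataclass
class HotspotRegion:
    """A merged run of loci that are both correlated and frequently altered."""

    direction: str
    chrom: str
    start: int
    end: int
    loci: list[str]
    n_genes: int
    avg_r: float
    avg_freq_pct: float


def select_hotspot_loci(
    correlations: list[LocusCorrelation],
    counts: pd.DataFrame,
    cutoffs: FrequencyCutoffs,
    direction: str,
) -> list[str]:
    """Loci that pass both filters for ``direction``, in counts-index order."""
    category = _CATEGORY[direction]
    cutoff = cutoffs.ug_cutoff if direction == UG else cutoffs.dl_cutoff
    significant = {c.locus for c in correlations if c.significant}
    col = counts[category]
    return [
        str(locus)
        for locus in counts.index
        if locus in significant and int(col[locus]) >= cutoff
    ]


def merge_into_regions(
    loci: list[str],
    track: FeatureTrack,
    correlations: list[LocusCorrelation],
    counts: pd.DataFrame,
    direction: str,
    n_samples: int,
    max_gap_loci: int = 1,
) -> list[HotspotRegion]:
    """Merge qualifying loci into regions and summarise them.

    ``track`` must be the gene-locus track; loci are merged along its order,
    allowing up to ``max_gap_loci`` intervening non-qualifying loci.
    """
    if not loci:
        return []
    index_of = track.index_of()
    rows = sorted(index_of[locus] for locus in loci)
    chroms = track.chroms
    r_by_locus = {c.locus: c.r for c in correlations}
    category = _CATEGORY[direction]

    groups: list[list[int]] = [[rows[0]]]
    for row in rows[1:]:
        prev = groups[-1][-1]
        if chroms[row] == chroms[prev] and (row - prev - 1) <= max_gap_loci:
            groups[-1].append(row)
        else:
            groups.append([row])

    regions = []
    for group in groups:
        ids = [str(track.ids[k]) for k in group]
        freqs = counts.loc[ids, category].to_numpy(dtype=float) / n_samples * 100.0
        regions.append(
            HotspotRegion(
                direction=direction,
                chrom=str(chroms[group[0]]),
                start=int(track.starts[group[0]]),
                end=int(track.ends[group[-1]]),
                loci=ids,
                n_genes=len(ids),
                avg_r=float(np.mean([r_by_locus[i] for i in ids])),
                avg_freq_pct=float(np.mean(freqs)),
            )
        )
    return regions


def _cytoband_labels(
    chrom: str, start: int, end: int, cytobands: pd.DataFrame | None
) -> str:
    if cytobands is None:
        return ""
    hits = cytobands[
        (cytobands["chrom"] == chrom)
        & (cytobands["start"] < end)
        & (cytobands["end"] > start)
    ]
    return ",".join(hits["id"].astype(str))


def region_report(
    regions: list[HotspotRegion],
    path: str,
    cytobands: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write the per-direction region table (Table 1/2 style) as TSV.

    Columns: region index, chrom, cytobands (annotation pass-through, empty
    unless a cytoband BED frame is supplied), start, end, avg_r,
    avg_freq_pct, n_genes, comma-joined gene symbols.
    """
    rows = []
    for k, region in enumerate(regions, start=1):
        rows.append(
            {
                "region": k,
                "chrom": region.chrom,
                "cytobands": _cytoband_labels(
                    region.chrom, region.start, region.end, cytobands
                ),
                "start": region.start,
                "end": region.end,
                "avg_r": round(region.avg_r, 6),
                "avg_freq_pct": round(region.avg_freq_pct, 6),
                "n_genes": region.n_genes,
                "genes": ",".join(region.loci),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "region",
            "chrom",
            "cytobands",
            "start",
            "end",
            "avg_r",
            "avg_freq_pct",
            "n_genes",
            "genes",
        ],
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_region_report(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "cytobands": str, "genes": str}
    )
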