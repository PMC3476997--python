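"""Core genomic containers: feature tracks, signal/ratio matrices, segments.

Coordinates are 0-based half-open (BED convention) everywhere, in files and
in memory.  Features are kept genomically sorted: chromosomes in natural
order (chr1..chr22, then chrX, chrY, anything else lexicographically), and
by start position within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CN_PROBE = "cn_probe"
GENE_LOCUS = "gene_locus"

TUMOR = "tumor"
NORMAL = "normal"


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering key (chr1 < chr2 < ... < chr22 < chrX < chrY)."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    upper = name.upper()
    if upper == "X":
        return (0, 23, "")
    if upper == "Y":
        return (0, 24, "")
    return (1, 0, name)


@dataclass
class FeatureTrack:
    """Genomically ordered features (CN probes or gene loci).

    Parameters
    ----------
    frame : DataFrame with columns ``id``, ``chrom``, ``start``, ``end``.
    kind : ``"cn_probe"`` or ``"gene_locus"``.
    """

    frame: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in (CN_PROBE, GENE_LOCUS):
            raise ValueError(f"unknown track kind: {self.kind!r}")
        required = ["id", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature frame missing columns {missing}")
        frame = self.frame.loc[:, required].copy()
        frame["id"] = frame["id"].astype(str)
        frame["chrom"] = frame["chrom"].astype(str)
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        if (frame["start"] > frame["end"]).any():
            bad = frame.loc[frame["start"] > frame["end"], "id"].iloc[0]
            raise ValueError(f"feature {bad!r} has start > end")
        if frame["id"].duplicated().any():
            dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicated feature id {dup!r}")
        order = sorted(
            range(len(frame)),
            key=lambda i: (chrom_sort_key(frame["chrom"].iat[i]), frame["start"].iat[i]),
        )
        frame = frame.iloc[order].reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, int]], kind: str
    ) -> "FeatureTrack":
        """Build from (id, chrom, start, end) tuples."""
        frame = pd.DataFrame(records, columns=["id", "chrom", "start", "end"])
        return cls(frame, kind)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.frame["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.frame["end"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        """Floor midpoint of each feature span."""
        return (self.starts + self.ends) // 2

    def index_of(self) -> dict[str, int]:
        return {fid: i for i, fid in enumerate(self.ids)}

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome, in genomic order."""
        chroms = self.chroms
        slices: dict[str, slice] = {}
        if len(chroms) == 0:
            return slices
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                slices[chroms[start]] = slice(start, i)
                start = i
        return slices

    def reorder_values(self, ids: Sequence[str], values: np.ndarray) -> np.ndarray:
        """Permute rows of ``values`` (indexed by ``ids``) into track order."""
        pos = {fid: i for i, fid in enumerate(ids)}
        perm = np.array([pos[fid] for fid in self.ids], dtype=int)
        return np.asarray(values)[perm]


@dataclass
class SignalMatrix:
    """Feature-by-sample matrix of positive normalized signals.

    ``sample_class`` labels each column ``"tumor"`` or ``"normal"``.
    """

    track: FeatureTrack
    samples: list[str]
    values: np.ndarray
    sample_class: list[str]

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.sample_class = [str(c) for c in self.sample_class]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.track):
            raise ValueError(
                f"row count {self.values.shape[0]} != feature count {len(self.track)}"
            )
        if self.values.shape[1] != len(self.samples):
            raise ValueError(
                f"column count {self.values.shape[1]} != sample count {len(self.samples)}"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        if len(self.sample_class) != len(self.samples):
            raise ValueError("sample_class length mismatch")
        bad = set(self.sample_class) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at feature {self.track.ids[r]!r}, sample {self.samples[c]!r}"
            )

    @property
    def tumor_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.sample_class) if c == TUMOR], dtype=int)

    @property
    def normal_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.sample_class) if c == NORMAL], dtype=int)

    @property
    def tumor_samples(self) -> list[str]:
        return [self.samples[i] for i in self.tumor_indices]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.track.ids, columns=self.samples)


@dataclass
class RatioMatrix:
    """Tumor-only feature-by-sample matrix in log2-ratio units."""

    track: FeatureTrack
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.track), len(self.samples)):
            raise ValueError("ratio matrix shape mismatch")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.track.ids, columns=self.samples)


@dataclass
class SegmentRecord:
    """One piecewise-constant segment of one sample's profile.

    ``seg_mean`` is the arithmetic mean log2 ratio over the member features;
    ``start``/``end`` span the first member's start to the last member's end.
    """

    sample: str
    chrom: str
    start: int
    end: int
    n_features: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("segment must contain at least one feature")
        if self.start > self.end:
            raise ValueError("segment start > end")


@dataclass
class SegmentedProfile:
    """Per-sample segmentation: segment records plus the per-feature vector.

    ``values[k]`` is the seg_mean of the segment containing feature ``k`` of
    ``track``; ``bounds`` holds the (chrom, lo, hi) feature-index span of each
    segment, parallel to ``segments``.
    """

    sample: str
    track: FeatureTrack
    segments: list[SegmentRecord]
    values: np.ndarray
    bounds: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.track):
            raise ValueError("segmented value vector length != track length")

    def chrom_segment_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per chromosome: (starts, ends, means) arrays in genomic order."""
        out: dict[str, list[list]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, [[], [], []])
            out[seg.chrom][0].append(seg.start)
            out[seg.chrom][1].append(seg.end)
            out[seg.chrom][2].append(seg.seg_mean)
        return {
            c: (np.asarray(v[0]), np.asarray(v[1]), np.asarray(v[2]))
            for c, v in out.items()
        }
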