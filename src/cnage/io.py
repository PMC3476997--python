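"""Readers and writers for the pipeline's tab-separated file formats.

Formats: TSV signal matrices (header row of sample ids, first column feature
ids), BED4 feature annotation (chrom, start, end, id), SEG segment files
(sample, chrom, start, end, num_features, seg_mean), and an optional
two-column sample-class table.  All coordinates are 0-based half-open; all
writers emit UTF-8, tab-delimited text with headers (BED files carry no
header, per convention).
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import (
    NORMAL,
    TUMOR,
    FeatureTrack,
    SegmentRecord,
    SignalMatrix,
    chrom_sort_key,
)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_features", "seg_mean"]


def read_bed4(path: str) -> pd.DataFrame:
    """Read BED4+ annotation into an (id, chrom, start, end) frame."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "id": str},
    )
    return frame[["id", "chrom", "start", "end"]]


def write_bed4(track: FeatureTrack, path: str) -> None:
    frame = track.frame[["chrom", "start", "end", "id"]]
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_sample_classes(path: str) -> dict[str, str]:
    """Read a two-column (sample, class) TSV; class is tumor or normal."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("sample class file needs two columns: sample, class")
    cols = list(frame.columns[:2])
    return dict(zip(frame[cols[0]], frame[cols[1]]))


def write_sample_classes(matrix: SignalMatrix, path: str) -> None:
    pd.DataFrame({"sample": matrix.samples, "class": matrix.sample_class}).to_csv(
        path, sep="\t", index=False
    )


def read_signal_matrix(
    path: str,
    annotation_path: str,
    kind: str,
    sample_classes: Mapping[str, str] | str | None = None,
) -> SignalMatrix:
    """Read a TSV signal matrix plus BED4 annotation into a SignalMatrix.

    Rows are reordered to genomic feature order.  Every matrix row id must be
    present in the annotation; non-numeric or missing cells are rejected.
    ``sample_classes`` maps sample id to ``tumor``/``normal`` (or is a path to
    a two-column TSV); samples not listed default to tumor.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric value at feature {row!r}, sample {col!r} in {path}"
            )
        if converted.isna().any():
            row = raw.index[converted.isna().to_numpy()][0]
            raise ValueError(f"missing value at feature {row!r}, sample {col!r}")
        values[:, j] = converted.to_numpy()

    annotation = read_bed4(annotation_path)
    known = set(annotation["id"])
    for fid in raw.index:
        if fid not in known:
            raise ValueError(f"feature {fid!r} has no annotation in {annotation_path}")
    annotation = annotation[annotation["id"].isin(set(raw.index))]
    track = FeatureTrack(annotation, kind)
    values = track.reorder_values(list(raw.index), values)

    if isinstance(sample_classes, str):
        sample_classes = read_sample_classes(sample_classes)
    classes = [
        (sample_classes or {}).get(s, TUMOR) for s in raw.columns
    ]
    unknown = [c for c in classes if c not in (TUMOR, NORMAL)]
    if unknown:
        raise ValueError(f"unknown sample class {unknown[0]!r}")
    return SignalMatrix(track, list(raw.columns), values, classes)


def write_signal_matrix(matrix: SignalMatrix, path: str) -> None:
    matrix.to_frame().rename_axis("feature").to_csv(path, sep="\t")


def _check_non_overlapping(segments: Sequence[SegmentRecord]) -> None:
    ordered = sorted(
        segments, key=lambda s: (s.sample, chrom_sort_key(s.chrom), s.start)
    )
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.sample == cur.sample and prev.chrom == cur.chrom and cur.start < prev.end:
            raise ValueError(
                f"overlapping segments for sample {cur.sample!r} on {cur.chrom}: "
                f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
            )


def write_segments(segments: Sequence[SegmentRecord], path: str) -> None:
    """Write segments as a SEG file (tab-separated, header, 0-based half-open)."""
    _check_non_overlapping(segments)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(SEG_COLUMNS) + "\n")
        for seg in segments:
            handle.write(
                f"{seg.sample}\t{seg.chrom}\t{seg.start}\t{seg.end}\t"
                f"{seg.n_features}\t{seg.seg_mean:.10f}\n"
            )


def read_segments(path: str) -> list[SegmentRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    return [
        SegmentRecord(
            sample=str(row["sample"]),
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            n_features=int(row["num_features"]),
            seg_mean=float(row["seg_mean"]),
        )
        for _, row in frame.iterrows()
    ]


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
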