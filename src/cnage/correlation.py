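"""Per-locus Pearson correlation of segmented CN and GE, with outlier rescue.

For each gene locus the segmented copy-number value is looked up at the
locus midpoint and matched with the locus's segmented expression value
across samples.  Pearson r gets a two-sided p from the t-transform
t = r * sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom, Bonferroni
corrected over the loci actually tested.  Significance is one-sided on the
coefficient itself (r >= r_threshold, default 0.60).

Gene loci whose raw (unsegmented) expression deviates strongly from their
expression segment mean in enough samples - typically dosage-responsive
genes sitting in a sparsely covered neighbourhood and flattened by
smoothing/segmentation - are re-tested with their raw expression against the
segmented copy number and, when they reach the same r threshold, added to
the significant set (never removing previously significant loci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import SegmentedProfile

SOURCE_SEGMENTED = "segmented"
SOURCE_RECOVERED = "outlier_recovered"


@dataclass
class LocusCorrelation:
    """Matched CN/GE pairs and the correlation test for one gene locus."""

    locus: str
    cn: np.ndarray
    ge: np.ndarray
    r: float
    p_raw: float
    p_adj: float
    source: str = SOURCE_SEGMENTED
    significant: bool = False


def segment_value_at_locus(
    profile: SegmentedProfile, chrom: str, midpoint: int
) -> float:
    """Segment mean covering ``midpoint`` on ``chrom`` (nearest segment if in a gap).

    Returns NaN when the chromosome is absent from the profile, which
    excludes the locus from testing.
    """
    arrays = profile.chrom_segment_arrays().get(chrom)
    if arrays is None:
        return math.nan
    starts, ends, means = arrays
    pos = int(np.searchsorted(starts, midpoint, side="right")) - 1
    if pos >= 0 and midpoint < ends[pos]:
        return float(means[pos])
    centers = (starts + ends) // 2
    return float(means[int(np.argmin(np.abs(centers - midpoint)))])


def _segment_lookup_table(profile: SegmentedProfile):
    return profile.chrom_segment_arrays()


def segment_values_at_loci(
    profile: SegmentedProfile, chroms: np.ndarray, midpoints: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`segment_value_at_locus` over many loci."""
    table = _segment_lookup_table(profile)
    out = np.full(len(chroms), np.nan)
    for chrom in np.unique(chroms):
        arrays = table.get(chrom)
        if arrays is None:
            continue
        starts, ends, means = arrays
        mask = chroms == chrom
        mids = midpoints[mask]
        pos = np.searchsorted(starts, mids, side="right") - 1
        inside = (pos >= 0) & (mids < ends[np.clip(pos, 0, len(ends) - 1)])
        vals = np.empty(mids.shape)
        vals[inside] = means[pos[inside]]
        if (~inside).any():
            centers = (starts + ends) // 2
            nearest = np.argmin(
                np.abs(centers[None, :] - mids[~inside, None]), axis=1
            )
            vals[~inside] = means[nearest]
        out[mask] = vals
    return out


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r; rows with zero variance (or NaNs) give NaN."""
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = x - np.nanmean(x, axis=1, keepdims=True)
        yc = y - np.nanmean(y, axis=1, keepdims=True)
        num = np.sum(xc * yc, axis=1)
        den = np.sqrt(np.sum(xc * xc, axis=1) * np.sum(yc * yc, axis=1))
        r = num / den
    r[np.isnan(x).any(axis=1) | np.isnan(y).any(axis=1)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def pearson_pvalue(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p for Pearson r via the t-transform with n-2 df."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p if p.ndim else float(p)


def pearson_threshold_pvalue(r: float, n: int, m: int = 1) -> float:
    """Bonferroni-adjusted two-sided p for coefficient ``r`` at sample size ``n``.

    ``m`` is the number of simultaneous locus tests.  For r = 0.60, n = 64
    and m = 20000 this is below 0.005, the usual genome-wide standard.
    """
    return float(min(1.0, m * pearson_pvalue(r, n)))


def correlate_loci(
    cn_values: pd.DataFrame,
    ge_values: pd.DataFrame,
    r_threshold: float = 0.60,
) -> list[LocusCorrelation]:
    """Pearson correlation of matched locus-by-sample CN and GE matrices.

    Both frames must share identical locus index and sample columns, with at
    least three samples.  Loci with zero variance in either vector (or with
    missing CN coverage) get an undefined r and are excluded from the
    Bonferroni family size m.
    """
    if list(cn_values.index) != list(ge_values.index):
        raise ValueError("locus sets of CN and GE matrices differ")
    if list(cn_values.columns) != list(ge_values.columns):
        raise ValueError("sample sets of CN and GE matrices differ")
    n = cn_values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples to correlate")
    cn = cn_values.to_numpy(dtype=float)
    ge = ge_values.to_numpy(dtype=float)
    r = _pearson_rows(cn, ge)
    defined = ~np.isnan(r)
    m = int(defined.sum())
    p_raw = np.full(len(r), np.nan)
    p_raw[defined] = pearson_pvalue(r[defined], n)
    p_adj = np.minimum(1.0, m * p_raw)
    out = []
    for k, locus in enumerate(cn_values.index):
        out.append(
            LocusCorrelation(
                locus=str(locus),
                cn=cn[k],
                ge=ge[k],
                r=float(r[k]),
                p_raw=float(p_raw[k]),
                p_adj=float(p_adj[k]),
                source=SOURCE_SEGMENTED,
                significant=bool(defined[k] and r[k] >= r_threshold),
            )
        )
    return out


def detect_segment_outlier_loci(
    ge_raw: pd.DataFrame,
    ge_profiles: dict[str, SegmentedProfile],
    min_fraction: float = 1.0 / 3.0,
    k_mad: float = 3.0,
) -> list[str]:
    """Gene loci whose raw expression escapes its segment in enough samples.

    A locus is flagged in one sample when |raw - seg_mean| exceeds ``k_mad``
    times the robust SD (1.4826 * MAD) of that segment's residuals; segments
    with fewer than 3 member loci cannot flag (MAD unstable).  Loci flagged
    in at least ceil(min_fraction * n_samples) samples are returned, in
    track order.
    """
    samples = list(ge_raw.columns)
    n_samples = len(samples)
    flags = np.zeros(len(ge_raw), dtype=int)
    raw = ge_raw.to_numpy(dtype=float)
    for col, sample in enumerate(samples):
        profile = ge_profiles[sample]
        resid = raw[:, col] - profile.values
        for _, lo, hi in profile.bounds:
            if hi - lo < 3:
                continue
            seg_resid = resid[lo:hi]
            mad = 1.4826 * np.median(np.abs(seg_resid - np.median(seg_resid)))
            flags[lo:hi] += np.abs(seg_resid) > k_mad * mad
    needed = math.ceil(min_fraction * n_samples)
    return [str(ge_raw.index[k]) for k in np.nonzero(flags >= needed)[0]]


def recover_outlier_correlations(
    outlier_loci: list[str],
    ge_raw: pd.DataFrame,
    cn_seg_values: pd.DataFrame,
    r_threshold: float = 0.60,
    m: int | None = None,
) -> list[LocusCorrelation]:
    """Re-test flagged loci: raw (unsegmented) GE against segmented CN.

    Returns one :class:`LocusCorrelation` per flagged locus with
    ``source="outlier_recovered"``; those reaching ``r_threshold`` are marked
    significant.  ``m`` is the Bonferroni family size used for ``p_adj``
    (defaults to the number of flagged loci).
    """
    if not outlier_loci:
        return []
    n = ge_raw.shape[1]
    ge = ge_raw.loc[outlier_loci].to_numpy(dtype=float)
    cn = cn_seg_values.loc[outlier_loci].to_numpy(dtype=float)
    r = _pearson_rows(cn, ge)
    m_eff = m if m is not None else len(outlier_loci)
    out = []
    for k, locus in enumerate(outlier_loci):
        defined = not np.isnan(r[k])
        p_raw = float(pearson_pvalue(r[k], n)) if defined else math.nan
        out.append(
            LocusCorrelation(
                locus=str(locus),
                cn=cn[k],
                ge=ge[k],
                r=float(r[k]),
                p_raw=p_raw,
                p_adj=min(1.0, m_eff * p_raw) if defined else math.nan,
                source=SOURCE_RECOVERED,
                significant=bool(defined and r[k] >= r_threshold),
            )
        )
    return out


def combine_correlations(
    primary: list[LocusCorrelation], recovered: list[LocusCorrelation]
) -> list[LocusCorrelation]:
    """Union of the segmented-correlation set and the rescued loci.

    A rescued significant locus replaces its (non-significant) segmented
    entry; loci already significant are never demoted.
    """
    by_locus = {c.locus: c for c in primary}
    for rec in recovered:
        current = by_locus.get(rec.locus)
        if rec.significant and (current is None or not current.significant):
            by_locus[rec.locus] = rec
    order = {c.locus: k for k, c in enumerate(primary)}
    extras = [c for c in by_locus.values() if c.locus not in order]
    merged = [by_locus[c.locus] for c in primary] + extras
    return merged


def correlation_frame(
    correlations: list[LocusCorrelation],
    chroms: dict[str, str] | None = None,
    midpoints: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tabular view (one row per locus) for reports."""
    rows = []
    for c in correlations:
        rows.append(
            {
                "locus": c.locus,
                "chrom": (chroms or {}).get(c.locus, ""),
                "midpoint": (midpoints or {}).get(c.locus, -1),
                "r": c.r,
                "p_raw": c.p_raw,
                "p_adj": c.p_adj,
                "source": c.source,
                "significant": c.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus",
            "chrom",
            "midpoint",
            "r",
            "p_raw",
            "p_adj",
            "source",
            "significant",
        ],
    )
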