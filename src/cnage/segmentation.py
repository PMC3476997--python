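"""Circular binary segmentation (CBS) of genomically ordered log2 ratios.

The same smoothing and segmentation is applied to copy-number probe tracks
and to gene-expression tracks (genes ordered by midpoint).  Each chromosome
of each sample is processed independently:

1. outlier smoothing: points deviating from their local window median by
   more than ``smooth_sd`` robust SDs are shrunk to the window median plus or
   minus ``smooth_sd`` SDs (sign preserving);
2. recursive circular splits: the arc (i, j] maximizing the two-sample
   t-like statistic |T| (arc mean vs complement mean, pooled variance) is
   tested with a permutation p-value; if p < alpha the segment is split into
   the 2-3 resulting pieces and recursion continues, otherwise it becomes a
   final segment whose mean is the arithmetic mean of its member values.

The permutation reference distribution is the max |T| over admissible arcs
of the permuted vector.  Because the total sum of squares is permutation
invariant, |T| is a monotone function of the arc's between-group sum of
squares BSS = g^2 * n / (k (n - k)) (g the centered arc sum, k the arc
length), so only the max BSS per permutation is computed.  Inside the
recursion a sequential permutation test is used: permutations are drawn in
blocks (capped at ``n_perm``) and stop as soon as a 99% Clopper-Pearson
interval for the p-value falls entirely below or above ``alpha``.  The
standalone :func:`split_pvalue` always runs the full ``n_perm``
permutations and returns (1 + exceedances)/(1 + n_perm).

Arcs touching either end of the segment reduce to ordinary binary splits.
Admissible arcs leave every resulting piece with at least ``min_width``
features.  Ties in |T| are broken by smallest i, then smallest j.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import beta as beta_dist

from .tracks import FeatureTrack, SegmentRecord, SegmentedProfile

# |T|^2 cap used when the pooled within-arc variance vanishes; permuted
# arrangements whose variance also vanishes exceed it and are counted.
_TSQ_CAP = 1e12
_REL_FLOOR = 1e-12


@dataclass
class CbsParams:
    """CBS tuning parameters (defaults mirror common DNAcopy usage).

    alpha : significance level for accepting a split.
    n_perm : permutation budget per split test.
    min_width : minimum number of features per segment.
    smooth_region : half-width of the outlier-smoothing window.
    smooth_sd : outlier threshold in robust-SD units.
    smooth : apply outlier smoothing before segmentation.
    seed : base seed; per-(sample, chromosome) streams are derived from it.
    """

    alpha: float = 0.01
    n_perm: int = 10000
    min_width: int = 2
    smooth_region: int = 10
    smooth_sd: float = 3.0
    smooth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


def smooth_outliers(values: np.ndarray, params: CbsParams | None = None) -> np.ndarray:
    """Shrink isolated outliers toward their local window median.

    A point is an outlier when it deviates from the median of its
    ``+-smooth_region`` window by more than ``smooth_sd`` times the window's
    SD; it is moved to median +- smooth_sd * SD, keeping the deviation's
    sign.  The SD is estimated from the window with the point itself
    excluded: a genuine run of shifted points then inflates its own
    window SD and is preserved, while an isolated spike against a quiet
    neighbourhood is shrunk.  Vectors shorter than the full window (2R+1)
    are returned unchanged.
    """
    params = params or CbsParams()
    v = np.asarray(values, dtype=float)
    n = len(v)
    radius = params.smooth_region
    width = 2 * radius + 1
    if n < width:
        return v.copy()
    out = v.copy()

    def _loo_sd(window: np.ndarray, center_value: float) -> float:
        m = len(window) - 1
        s = window.sum() - center_value
        q = float(np.dot(window, window)) - center_value * center_value
        var = (q - s * s / m) / (m - 1)
        return float(np.sqrt(max(var, 0.0)))

    windows = np.lib.stride_tricks.sliding_window_view(v, width)
    centers = np.arange(radius, n - radius)
    med = np.median(windows, axis=1)
    m = width - 1
    s = windows.sum(axis=1) - v[centers]
    q = (windows * windows).sum(axis=1) - v[centers] ** 2
    sd = np.sqrt(np.maximum((q - s * s / m) / (m - 1), 0.0))
    dev = v[centers] - med
    lim = params.smooth_sd * sd
    mask = np.abs(dev) > lim
    out[centers[mask]] = med[mask] + np.sign(dev[mask]) * lim[mask]

    for i in list(range(radius)) + list(range(n - radius, n)):
        lo, hi = max(0, i - radius), min(n, i + radius + 1)
        window = v[lo:hi]
        wmed = np.median(window)
        wsd = _loo_sd(window, v[i])
        d = v[i] - wmed
        wlim = params.smooth_sd * wsd
        if abs(d) > wlim:
            out[i] = wmed + np.sign(d) * wlim
    return out


@lru_cache(maxsize=256)
def _arc_geometry(n: int, min_width: int):
    """Flattened admissible (i, j) arc pairs and the BSS coefficient n/(k(n-k)).

    An arc (i, j] is admissible when the arc and every non-empty complement
    piece ([0, i) and [j, n)) have at least ``min_width`` features.  Pairs
    are ordered row-major in (i, j) so that argmax tie-breaking picks the
    smallest i, then the smallest j.
    """
    idx = np.arange(n + 1)
    i_mat = idx[:, None]
    j_mat = idx[None, :]
    k = j_mat - i_mat
    ok = (k >= min_width) & ((n - k) >= min_width)
    ok &= (i_mat == 0) | (i_mat >= min_width)
    ok &= (j_mat == n) | ((n - j_mat) >= min_width)
    ii, jj = np.nonzero(ok)
    kk = (jj - ii).astype(float)
    coef = n / (kk * (n - kk))
    return ii, jj, coef


def _tsq_from_bss(bss: float, tss: float, n: int) -> float:
    """T^2 of an arc from its between-group SS and the total SS."""
    within = tss - bss
    if within <= _REL_FLOOR * max(tss, 1.0):
        return _TSQ_CAP if bss > 0 else 0.0
    return min(bss * (n - 2) / within, _TSQ_CAP)


def _bss_threshold(t_obs: float, tss: float, n: int) -> float:
    """BSS level equivalent to |T| >= |t_obs| (monotone transform)."""
    tsq = min(t_obs * t_obs, _TSQ_CAP)
    return tss * tsq / ((n - 2) + tsq) * (1.0 - 1e-10)


def best_circular_split(values: np.ndarray, min_width: int = 2) -> tuple[int, int, float]:
    """Arc (i, j] maximizing |T|; returns (i, j, signed T).

    A vector with (numerically) zero overall variance, or too short to admit
    any arc, returns (0, n, 0.0).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        return 0, n, 0.0
    centered = v - v.mean()
    tss = float(np.dot(centered, centered))
    if tss <= _REL_FLOOR * max(1.0, float(np.dot(v, v))):
        return 0, n, 0.0
    geom = _arc_geometry(n, min_width)
    if geom[0].size == 0:
        return 0, n, 0.0
    ii, jj, coef = geom
    s = np.concatenate(([0.0], np.cumsum(centered)))
    g = s[jj] - s[ii]
    bss = g * g * coef
    # complementary arcs define the same partition with identical |T|; take
    # the first (smallest i, then j) among near-ties to stay deterministic
    top = float(bss.max())
    best = int(np.argmax(bss >= top * (1.0 - 1e-9)))
    t_abs = float(np.sqrt(_tsq_from_bss(float(bss[best]), tss, n)))
    return int(ii[best]), int(jj[best]), float(np.sign(g[best]) * t_abs)


def _perm_max_bss(
    centered: np.ndarray, n_draws: int, min_width: int, rng: np.random.Generator
) -> np.ndarray:
    """Max arc BSS for ``n_draws`` random permutations of the centered vector."""
    n = len(centered)
    ii, jj, coef = _arc_geometry(n, min_width)
    out = np.empty(n_draws)
    block = max(16, int(6e6 / max(len(ii), 1)))
    done = 0
    while done < n_draws:
        b = min(block, n_draws - done)
        perm = rng.permuted(np.tile(centered, (b, 1)), axis=1)
        s = np.concatenate((np.zeros((b, 1)), np.cumsum(perm, axis=1)), axis=1)
        g = s[:, jj]
        g -= s[:, ii]
        np.multiply(g, g, out=g)
        g *= coef
        out[done : done + b] = g.max(axis=1)
        done += b
    return out


def split_pvalue(
    values: np.ndarray,
    t_obs: float,
    params: CbsParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Full-permutation p-value for the observed max |T|.

    p = (1 + #{permutations with max |T| >= |T_obs|}) / (1 + n_perm),
    deterministic for a given seed.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    v = np.asarray(values, dtype=float)
    n = len(v)
    if _arc_geometry(n, params.min_width)[0].size == 0:
        return 1.0
    centered = v - v.mean()
    tss = float(np.dot(centered, centered))
    if tss <= _REL_FLOOR * max(1.0, float(np.dot(v, v))):
        return 1.0
    threshold = _bss_threshold(t_obs, tss, n)
    maxima = _perm_max_bss(centered, params.n_perm, params.min_width, rng)
    exceed = int(np.count_nonzero(maxima >= threshold))
    return (1 + exceed) / (1 + params.n_perm)


def _split_is_significant(
    v: np.ndarray, t_obs: float, params: CbsParams, rng: np.random.Generator
) -> bool:
    """Sequential permutation decision of p < alpha (capped at n_perm draws)."""
    centered = v - v.mean()
    tss = float(np.dot(centered, centered))
    threshold = _bss_threshold(t_obs, tss, len(v))
    drawn = 0
    exceed = 0
    block = 128
    while drawn < params.n_perm:
        b = min(block, params.n_perm - drawn)
        maxima = _perm_max_bss(centered, b, params.min_width, rng)
        exceed += int(np.count_nonzero(maxima >= threshold))
        drawn += b
        upper = (
            float(beta_dist.ppf(0.995, exceed + 1, drawn - exceed))
            if exceed < drawn
            else 1.0
        )
        lower = (
            float(beta_dist.ppf(0.005, exceed, drawn - exceed + 1))
            if exceed > 0
            else 0.0
        )
        if upper < params.alpha:
            return True
        if lower > params.alpha:
            return False
        block = min(block * 2, 2048)
    return (1 + exceed) / (1 + params.n_perm) < params.alpha


def _segment_chrom(
    v: np.ndarray, params: CbsParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's ordered values; (lo, hi) partition."""
    final: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = [(0, len(v))]
    while stack:
        lo, hi = stack.pop()
        m = hi - lo
        if m < 2 * params.min_width:
            final.append((lo, hi))
            continue
        i, j, t = best_circular_split(v[lo:hi], params.min_width)
        if t == 0.0 or not _split_is_significant(v[lo:hi], t, params, rng):
            final.append((lo, hi))
            continue
        pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
        for piece in reversed(pieces):
            if piece[1] > piece[0]:
                stack.append(piece)
    return sorted(final)


def _sample_chrom_rng(seed: int, sample: str, chrom_rank: int) -> np.random.Generator:
    # keyed on the sample *id* so reordering samples never changes a profile
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(sample.encode("utf-8")), chrom_rank])
    )


def cbs_segment(
    track: FeatureTrack,
    values: np.ndarray,
    params: CbsParams | None = None,
    sample: str = "sample",
) -> SegmentedProfile:
    """Smooth and segment one sample's values aligned to ``track``.

    Returns a :class:`SegmentedProfile` whose per-feature vector assigns each
    feature its segment's mean.  Chromosomes are processed independently with
    reproducible per-(sample, chromosome) random streams.
    """
    params = params or CbsParams()
    values = np.asarray(values, dtype=float)
    if len(values) != len(track):
        raise ValueError("values not aligned to track")
    out = np.empty(len(values))
    segments: list[SegmentRecord] = []
    bounds: list[tuple[str, int, int]] = []
    starts, ends = track.starts, track.ends
    for rank, (chrom, sl) in enumerate(track.chrom_slices().items()):
        v = values[sl]
        vs = smooth_outliers(v, params) if params.smooth else v
        rng = _sample_chrom_rng(params.seed, sample, rank)
        for lo, hi in _segment_chrom(vs, params, rng):
            mean = float(vs[lo:hi].mean())
            out[sl][lo:hi] = mean
            glo, ghi = sl.start + lo, sl.start + hi
            segments.append(
                SegmentRecord(
                    sample=sample,
                    chrom=chrom,
                    start=int(starts[glo]),
                    end=int(ends[ghi - 1]),
                    n_features=hi - lo,
                    seg_mean=mean,
                )
            )
            bounds.append((chrom, glo, ghi))
    return SegmentedProfile(sample, track, segments, out, bounds)
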