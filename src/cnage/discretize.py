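"""Data-driven 3-state discretization and alteration-frequency analysis.

Gain/Loss and Up/Down thresholds are derived by exact 1-D k-means (k = 3) on
the pooled segmented locus-by-sample values of each data type.  Sorted 1-D
data admit contiguous optimal clusters, so the global optimum is found by a
divide-and-conquer boundary search (no random initialisation, hence no
seed-dependence).  Each boundary threshold is the midpoint between the
adjacent clusters' extreme members; values strictly above the upper
threshold are Gain/Up, strictly below the lower one Loss/Down, and boundary
equality is no-change.

Per locus, samples are tallied over the 9 joint states
(U-G, N-G, D-G, U-N, N-N, D-N, U-L, N-L, D-L) and the frequency cutoff for
each concordant direction (U-G, D-L) is the upper 10% empirical quantile
(type-1 nearest rank) of the per-locus counts, floored at one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ["U-G", "N-G", "D-G", "U-N", "N-N", "D-N", "U-L", "N-L", "D-L"]

GAIN, NEUTRAL, LOSS = 1, 0, -1


@dataclass
class DiscretizationThresholds:
    """Gain/loss and up/down cut values, in log2-ratio units."""

    cn_gain: float
    cn_loss: float
    ge_up: float
    ge_down: float

    def __post_init__(self) -> None:
        if not self.cn_loss < self.cn_gain:
            raise ValueError("cn_loss must be below cn_gain")
        if not self.ge_down < self.ge_up:
            raise ValueError("ge_down must be below ge_up")


@dataclass
class FrequencyCutoffs:
    """Sample-count cutoffs for the concordant categories."""

    ug_cutoff: int
    dl_cutoff: int
    quantile: float = 0.90


def _prefix_cost(sorted_values: np.ndarray):
    s = np.concatenate(([0.0], np.cumsum(sorted_values)))
    q = np.concatenate(([0.0], np.cumsum(sorted_values * sorted_values)))

    def cost(i, j):
        i = np.asarray(i)
        j = np.asarray(j)
        width = (j - i).astype(float)
        seg_sum = s[j] - s[i]
        return (q[j] - q[i]) - seg_sum * seg_sum / width

    return cost


def exact_kmeans3(values: np.ndarray) -> tuple[int, int, float]:
    """Globally optimal 1-D 3-means on sorted data.

    Returns boundaries (b1, b2) so the sorted clusters are
    x[:b1], x[b1:b2], x[b2:], plus the within-cluster sum of squares.
    Uses the monotone-argmin divide-and-conquer over the two-cluster
    subproblem (the squared-error cost is concave-Monge).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if len(np.unique(x)) < 3:
        raise ValueError("k-means with k=3 needs at least 3 distinct values")
    cost = _prefix_cost(x)

    d2 = np.full(n + 1, np.inf)
    arg1 = np.zeros(n + 1, dtype=int)
    # d2[m]: optimal 2-cluster cost of x[:m]; argmin is monotone in m
    stack = [(2, n - 1, 1, n - 2)]
    while stack:
        mlo, mhi, blo, bhi = stack.pop()
        if mlo > mhi:
            continue
        mid = (mlo + mhi) // 2
        cands = np.arange(blo, min(bhi, mid - 1) + 1)
        vals = cost(0, cands) + cost(cands, mid)
        t = int(np.argmin(vals))
        d2[mid] = float(vals[t])
        arg1[mid] = int(cands[t])
        stack.append((mlo, mid - 1, blo, arg1[mid]))
        stack.append((mid + 1, mhi, arg1[mid], bhi))

    b2_cands = np.arange(2, n)
    totals = d2[b2_cands] + cost(b2_cands, n)
    t = int(np.argmin(totals))
    b2 = int(b2_cands[t])
    b1 = int(arg1[b2])
    return b1, b2, float(totals[t])


def kmeans3_thresholds(values: np.ndarray) -> tuple[float, float]:
    """(lower, upper) cut values from exact 3-means on the pooled vector.

    The lower threshold is the midpoint between the low cluster's maximum and
    the middle cluster's minimum; the upper threshold likewise between the
    middle and high clusters.
    """
    x = np.sort(np.asarray(values, dtype=float))
    b1, b2, _ = exact_kmeans3(x)
    lower = 0.5 * (x[b1 - 1] + x[b1])
    upper = 0.5 * (x[b2 - 1] + x[b2])
    return float(lower), float(upper)


def assign_states(values: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Three-state calls: 1 above ``upper``, -1 below ``lower``, else 0.

    Boundary equality is classified as no-change (strict inequalities).
    """
    v = np.asarray(values, dtype=float)
    return np.where(v > upper, GAIN, np.where(v < lower, LOSS, NEUTRAL)).astype(np.int8)


def joint_category_counts(
    cn_states: np.ndarray, ge_states: np.ndarray, loci: list[str]
) -> pd.DataFrame:
    """Per-locus sample counts over the 9 joint (GE, CN) states.

    Rows are loci, columns the categories in canonical order; every row sums
    to the number of samples.
    """
    cn = np.asarray(cn_states)
    ge = np.asarray(ge_states)
    if cn.shape != ge.shape:
        raise ValueError("CN and GE state matrices must have identical shape")
    if cn.shape[0] != len(loci):
        raise ValueError("locus list length mismatch")
    # category index: columns G,N,L (by CN) x rows U,N,D (by GE)
    cat = (1 - cn.astype(int)) * 3 + (1 - ge.astype(int))
    n_loci = cn.shape[0]
    offset = cat + 9 * np.arange(n_loci)[:, None]
    counts = np.bincount(offset.ravel(), minlength=9 * n_loci).reshape(n_loci, 9)
    return pd.DataFrame(counts, index=list(loci), columns=CATEGORIES)


def _nearest_rank_quantile(values: np.ndarray, quantile: float) -> int:
    ordered = np.sort(np.asarray(values))
    rank = max(1, math.ceil(quantile * len(ordered)))
    return int(ordered[rank - 1])


def frequency_cutoffs(
    counts: pd.DataFrame, quantile: float = 0.90, min_cutoff: int = 1
) -> FrequencyCutoffs:
    """Upper-quantile sample-count cutoffs for U-G and D-L.

    Uses the type-1 nearest-rank empirical quantile of the per-locus counts
    (counts are discrete), floored at ``min_cutoff`` so a qualifying locus is
    altered in at least one sample.  Requires at least 10 loci.
    """
    if len(counts) < 10:
        raise ValueError("need at least 10 loci to estimate frequency cutoffs")
    ug = max(min_cutoff, _nearest_rank_quantile(counts["U-G"].to_numpy(), quantile))
    dl = max(min_cutoff, _nearest_rank_quantile(counts["D-L"].to_numpy(), quantile))
    return FrequencyCutoffs(ug_cutoff=ug, dl_cutoff=dl, quantile=quantile)
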