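"""Log2-ratio construction against the median of the normal samples.

Each tumor value is divided by the median of the normal samples for the same
feature and log2-transformed, so a tumor value equal to the normals' median
maps to exactly 0.  The normals' median uses the midpoint-of-two rule for
even counts.
"""

from __future__ import annotations

import numpy as np

from .tracks import RatioMatrix, SignalMatrix


def to_log2_ratio(matrix: SignalMatrix) -> RatioMatrix:
    """Convert positive signals to tumor-only log2 ratios vs the normal median.

    Raises
    ------
    ValueError
        If there is no normal sample or any signal value is non-positive.
    """
    normals = matrix.normal_indices
    if normals.size == 0:
        raise ValueError("at least one normal sample is required to build ratios")
    if (matrix.values <= 0).any():
        r, c = np.argwhere(matrix.values <= 0)[0]
        raise ValueError(
            f"non-positive signal at feature {matrix.track.ids[r]!r}, "
            f"sample {matrix.samples[c]!r}"
        )
    median = np.median(matrix.values[:, normals], axis=1)
    tumors = matrix.tumor_indices
    ratios = np.log2(matrix.values[:, tumors] / median[:, None])
    return RatioMatrix(matrix.track, matrix.tumor_samples, ratios)


def passthrough_log2_ratio(matrix: SignalMatrix) -> RatioMatrix:
    """Treat the tumor columns as already being log2 ratios (no normalization).

    Used when input matrices ship pre-computed log ratios
    (``normalization.enabled: false`` in the run configuration).
    """
    tumors = matrix.tumor_indices
    return RatioMatrix(matrix.track, matrix.tumor_samples, matrix.values[:, tumors])
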