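import numpy as np
import pytest

from cnage import FeatureTrack, SignalMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20120919)


@pytest.fixture
def small_track():
    return FeatureTrack.from_records(
        [
            ("g1", "chr1", 0, 100),
            ("g2", "chr1", 200, 300),
            ("g3", "chr2", 50, 150),
        ],
        "gene_locus",
    )


@pytest.fixture
def small_matrix(small_track):
    values = np.array([[2.0, 4.0, 1.0], [1.0, 1.0, 1.0], [0.5, 2.0, 2.0]])
    return SignalMatrix(
        small_track, ["t1", "t2", "n1"], values, ["tumor", "tumor", "normal"]
    )


def uniform_track(n, chrom="chr1", kind="cn_probe", spacing=1000, span=25, prefix="p"):
    return FeatureTrack.from_records(
        [(f"{prefix}{i:04d}", chrom, i * spacing, i * spacing + span) for i in range(n)],
        kind,
    )
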