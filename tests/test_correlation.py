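import math

import numpy as np
import pandas as pd
import pytest

from cnage import (
    SegmentedProfile,
    correlate_loci,
    detect_segment_outlier_loci,
    pearson_threshold_pvalue,
    recover_outlier_correlations,
    segment_value_at_locus,
)
from cnage.correlation import combine_correlations, segment_values_at_loci
from cnage.tracks import SegmentRecord
from conftest import uniform_track


def _profile(track, segment_spans):
    """Build a SegmentedProfile from (chrom, start, end, mean) tuples."""
    segments = [
        SegmentRecord("s", chrom, start, end, 1, mean)
        for chrom, start, end, mean in segment_spans
    ]
    return SegmentedProfile("s", track, segments, np.zeros(len(track)), [])


class TestSegmentLookup:
    def test_whole_chromosome_segment(self, small_track):
        profile = _profile(small_track, [("chr1", 0, 1000, 0.3)])
        assert segment_value_at_locus(profile, "chr1", 500) == 0.3

    def test_containment_beats_proximity(self, small_track):
        profile = _profile(
            small_track, [("chr1", 0, 100, 0.0), ("chr1", 100, 200, 1.0)]
        )
        # locus (90, 130) has midpoint 110, inside the second segment
        assert segment_value_at_locus(profile, "chr1", 110) == 1.0

    def test_gap_falls_back_to_nearest_segment(self, small_track):
        profile = _profile(
            small_track, [("chr1", 0, 100, 0.0), ("chr1", 300, 400, 1.0)]
        )
        assert segment_value_at_locus(profile, "chr1", 120) == 0.0
        assert segment_value_at_locus(profile, "chr1", 280) == 1.0

    def test_missing_chromosome_gives_nan(self, small_track):
        profile = _profile(small_track, [("chr1", 0, 100, 0.0)])
        assert math.isnan(segment_value_at_locus(profile, "chr7", 50))

    def test_vectorised_lookup_matches_linear_scan(self, rng):
        track = uniform_track(30)
        for _ in range(10):
            cuts = np.sort(rng.choice(np.arange(100, 3000, 100), 4, replace=False))
            spans = []
            prev = 0
            for k, cut in enumerate(list(cuts) + [3100]):
                spans.append(("chr1", prev, int(cut), float(rng.normal())))
                prev = int(cut)
            profile = _profile(track, spans)
            mids = rng.integers(0, 3200, size=20)
            got = segment_values_at_loci(
                profile, np.array(["chr1"] * 20), np.asarray(mids)
            )
            for mid, value in zip(mids, got):
                # independent linear-scan oracle over the segment list
                containing = [
                    m for c, s, e, m in spans if s <= mid < e
                ]
                if containing:
                    expected = containing[0]
                else:
                    expected = min(
                        spans, key=lambda t: abs((t[1] + t[2]) // 2 - mid)
                    )[3]
                assert value == expected


class TestCorrelateLoci:
    def test_affine_relation_gives_perfect_correlation(self):
        cn = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=["g"], columns=list("abcd"))
        ge = 2.0 * cn + 1.0
        (result,) = correlate_loci(cn, ge)
        assert result.r == pytest.approx(1.0)
        assert result.p_raw == pytest.approx(0.0, abs=1e-12)
        assert result.significant

    def test_perfect_anticorrelation(self):
        cn = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=["g"], columns=list("abcd"))
        ge = pd.DataFrame([[3.0, 2.0, 1.0, 0.0]], index=["g"], columns=list("abcd"))
        (result,) = correlate_loci(cn, ge)
        assert result.r == pytest.approx(-1.0)
        assert not result.significant  # selection is one-sided on r

    def test_threshold_pvalue_consistent_with_printed_bound(self):
        # r = 0.60 at n = 64, Bonferroni over 20000 loci stays under 0.005
        p_adj = pearson_threshold_pvalue(0.60, 64, m=20000)
        assert p_adj < 0.005
        # the raw p agrees with an independent t-distribution evaluation
        from scipy.stats import t as t_dist

        t = 0.60 * math.sqrt(62) / math.sqrt(1 - 0.36)
        assert pearson_threshold_pvalue(0.60, 64) == pytest.approx(
            2 * t_dist.sf(t, 62), rel=1e-12
        )

    def test_zero_variance_locus_excluded_from_family(self, rng):
        cn = pd.DataFrame(
            np.vstack([np.ones(6), rng.normal(size=6)]),
            index=["flat", "ok"],
            columns=list("abcdef"),
        )
        ge = pd.DataFrame(
            rng.normal(size=(2, 6)), index=["flat", "ok"], columns=list("abcdef")
        )
        flat, ok = correlate_loci(cn, ge)
        assert math.isnan(flat.r) and not flat.significant
        # m = 1, so p_adj equals p_raw for the surviving locus
        assert ok.p_adj == pytest.approx(min(1.0, ok.p_raw))

    def test_mismatched_samples_rejected(self):
        cn = pd.DataFrame(np.zeros((1, 3)), index=["g"], columns=list("abc"))
        ge = pd.DataFrame(np.zeros((1, 3)), index=["g"], columns=list("abd"))
        with pytest.raises(ValueError, match="sample sets"):
            correlate_loci(cn, ge)

    def test_affine_rescaling_invariance(self, rng):
        cn = pd.DataFrame(rng.normal(size=(4, 10)), columns=[f"s{i}" for i in range(10)])
        ge = pd.DataFrame(rng.normal(size=(4, 10)), columns=[f"s{i}" for i in range(10)])
        base = [c.r for c in correlate_loci(cn, ge)]
        scaled = [c.r for c in correlate_loci(cn * 3.5 + 1.0, ge * 0.2 - 7.0)]
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_t_transform_agrees_with_permutation_p(self, rng):
        # dual route: analytic p vs a 10000-draw permutation p on one locus
        n = 12
        cn_row = rng.normal(size=n)
        ge_row = 0.8 * cn_row + rng.normal(0, 1.0, size=n)
        cn = pd.DataFrame([cn_row], index=["g"], columns=[f"s{i}" for i in range(n)])
        ge = pd.DataFrame([ge_row], index=["g"], columns=[f"s{i}" for i in range(n)])
        (result,) = correlate_loci(cn, ge)
        draws = 10000
        perm_rng = np.random.default_rng(5)
        count = 0
        for _ in range(draws):
            r = np.corrcoef(cn_row, perm_rng.permutation(ge_row))[0, 1]
            count += abs(r) >= abs(result.r) - 1e-12
        p_perm = (1 + count) / (1 + draws)
        assert p_perm == pytest.approx(result.p_raw, abs=0.01)


def _flat_profiles(track, raw, offset_locus=None, offset_samples=(), offset=0.0):
    """Whole-chromosome single-segment profiles whose mean ignores the offset."""
    profiles = {}
    for col, sample in enumerate(raw.columns):
        values = np.zeros(len(track))
        profiles[sample] = SegmentedProfile(
            sample,
            track,
            [SegmentRecord(sample, "chr1", 0, 10**9, len(track), 0.0)],
            values,
            [("chr1", 0, len(track))],
        )
    return profiles


class TestOutlierDetection:
    def _fixture(self, n_loci=20, n_samples=64, offset=5.0, n_offset=30, seed=0):
        gen = np.random.default_rng(seed)
        track = uniform_track(n_loci, kind="gene_locus", prefix="g")
        samples = [f"s{i}" for i in range(n_samples)]
        raw = pd.DataFrame(
            gen.normal(0, 0.05, size=(n_loci, n_samples)),
            index=track.ids,
            columns=samples,
        )
        raw.iloc[7, :n_offset] += offset
        profiles = _flat_profiles(track, raw)
        return track, raw, profiles

    def test_raw_equal_to_segmented_flags_nothing(self):
        track = uniform_track(10, kind="gene_locus", prefix="g")
        raw = pd.DataFrame(
            np.zeros((10, 6)), index=track.ids, columns=[f"s{i}" for i in range(6)]
        )
        profiles = _flat_profiles(track, raw)
        assert detect_segment_outlier_loci(raw, profiles) == []

    def test_locus_offset_in_enough_samples_is_flagged(self):
        track, raw, profiles = self._fixture(n_offset=30)
        # hand oracle: ceil(64/3) = 22 <= 30 flagged samples
        assert detect_segment_outlier_loci(raw, profiles) == [str(track.ids[7])]

    def test_locus_offset_in_too_few_samples_is_not_flagged(self):
        _, raw, profiles = self._fixture(n_offset=10)
        assert detect_segment_outlier_loci(raw, profiles) == []

    def test_small_segments_cannot_flag(self):
        track = uniform_track(2, kind="gene_locus", prefix="g")
        raw = pd.DataFrame(
            np.array([[5.0] * 6, [0.0] * 6]),
            index=track.ids,
            columns=[f"s{i}" for i in range(6)],
        )
        profiles = {}
        for sample in raw.columns:
            profiles[sample] = SegmentedProfile(
                sample,
                track,
                [SegmentRecord(sample, "chr1", 0, 10**9, 2, 0.0)],
                np.zeros(2),
                [("chr1", 0, 2)],
            )
        assert detect_segment_outlier_loci(raw, profiles) == []


class TestOutlierRecovery:
    def test_raw_tracking_cn_exactly_is_recovered(self):
        samples = [f"s{i}" for i in range(8)]
        cn = pd.DataFrame([[0, 0, 1, 1, 0, 1, 0, 1]], index=["g"], columns=samples, dtype=float)
        ge = cn * 0.8
        (rec,) = recover_outlier_correlations(["g"], ge, cn)
        assert rec.r == pytest.approx(1.0)
        assert rec.significant and rec.source == "outlier_recovered"

    def test_independent_raw_ge_is_not_recovered(self, rng):
        samples = [f"s{i}" for i in range(64)]
        cn = pd.DataFrame([rng.normal(size=64)], index=["g"], columns=samples)
        ge = pd.DataFrame([rng.normal(size=64)], index=["g"], columns=samples)
        (rec,) = recover_outlier_correlations(["g"], ge, cn)
        assert abs(rec.r) < 0.60
        assert not rec.significant

    def test_significant_set_only_grows(self, rng):
        samples = [f"s{i}" for i in range(10)]
        loci = [f"g{i}" for i in range(6)]
        cn = pd.DataFrame(rng.normal(size=(6, 10)), index=loci, columns=samples)
        ge = pd.DataFrame(rng.normal(size=(6, 10)), index=loci, columns=samples)
        ge.iloc[0] = cn.iloc[0] * 1.1  # one clearly coupled locus
        primary = correlate_loci(cn, ge)
        before = {c.locus for c in primary if c.significant}
        recovered = recover_outlier_correlations(loci[:3], ge, cn)
        merged = combine_correlations(primary, recovered)
        after = {c.locus for c in merged if c.significant}
        assert after >= before
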