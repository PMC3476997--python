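import numpy as np
import pytest

from cnage import CbsParams, best_circular_split, cbs_segment, smooth_outliers, split_pvalue
from conftest import uniform_track


def exhaustive_best_arc(v, min_width=2):
    """Independent brute-force scan of all admissible circular arcs.

    Returns (i, j, T) with ties broken by smallest i then smallest j.
    """
    v = np.asarray(v, dtype=float)
    n = len(v)
    if np.allclose(v, v[0]):
        return 0, n, 0.0
    candidates = []  # (i, j, T, score) in row-major (i, j) order
    for i in range(0, n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            if i != 0 and i < min_width:
                continue
            if j != n and n - j < min_width:
                continue
            arc = v[i:j]
            rest = np.concatenate([v[:i], v[j:]])
            diff = arc.mean() - rest.mean()
            rss = ((arc - arc.mean()) ** 2).sum() + ((rest - rest.mean()) ** 2).sum()
            if rss <= 1e-12 * max(1.0, float(np.dot(v, v))):
                score = 1e12 if diff != 0 else 0.0
            else:
                score = min(diff * diff * (n - 2) / (rss * (1 / k + 1 / (n - k))), 1e12)
            candidates.append((i, j, float(np.sign(diff) * np.sqrt(score)), score))
    if not candidates:
        return 0, n, 0.0
    top = max(c[3] for c in candidates)
    # first near-tie wins: complementary arcs describe the same partition
    for i, j, t, score in candidates:
        if score >= top * (1 - 1e-9):
            return i, j, t
    raise AssertionError("unreachable")


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        v = np.full(30, 0.7)
        np.testing.assert_array_equal(smooth_outliers(v), v)

    def test_central_spike_is_shrunk_zeros_untouched(self):
        v = np.zeros(21)
        v[10] = 10.0
        out = smooth_outliers(v, CbsParams(smooth_region=10, smooth_sd=3.0))
        # direct evaluation of the windowed rule: window median 0, MAD 0,
        # so the spike collapses to the median and no other point moves
        assert out[10] == pytest.approx(0.0)
        np.testing.assert_array_equal(out[:10], np.zeros(10))
        np.testing.assert_array_equal(out[11:], np.zeros(10))

    def test_vector_shorter_than_window_unchanged(self, rng):
        v = rng.normal(size=15)
        v[7] = 50.0
        np.testing.assert_array_equal(
            smooth_outliers(v, CbsParams(smooth_region=10)), v
        )

    def test_moderate_points_untouched_with_noise(self, rng):
        v = rng.normal(0, 1.0, size=51)
        out = smooth_outliers(v, CbsParams(smooth_region=10, smooth_sd=3.0))
        unchanged = out == v
        assert unchanged.mean() > 0.9  # only rare extremes move


class TestBestCircularSplit:
    def test_step_isolates_the_high_arc(self):
        i, j, t = best_circular_split(np.array([0.0, 0, 0, 0, 5, 5, 5, 5]))
        # the two complementary arcs tie in |T|; either isolates the four 5s
        assert (i, j) in {(0, 4), (4, 8)}
        assert (i, j, np.sign(t)) == exhaustive_best_arc([0, 0, 0, 0, 5, 5, 5, 5])[:2] + (
            np.sign(exhaustive_best_arc([0, 0, 0, 0, 5, 5, 5, 5])[2]),
        )

    def test_constant_vector_gives_zero_statistic(self):
        i, j, t = best_circular_split(np.full(10, 2.5))
        assert (i, j, t) == (0, 10, 0.0)

    def test_min_width_honoured_against_brute_force(self):
        v = np.array([1.0, 9.0, 1.0, 1.0, 1.0, 1.0])
        assert best_circular_split(v, min_width=2)[:2] == exhaustive_best_arc(v, 2)[:2]

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_oracle_on_random_vectors(self, trial):
        gen = np.random.default_rng(1000 + trial)
        n = int(gen.integers(4, 41))
        v = gen.normal(size=n)
        if trial % 3 == 0:  # sometimes add a real step
            a, b = sorted(gen.integers(0, n, size=2))
            v[a:b] += 2.0
        i, j, t = best_circular_split(v)
        oi, oj, ot = exhaustive_best_arc(v)
        assert (i, j) == (oi, oj)
        assert t == pytest.approx(ot, rel=1e-8)


class TestSplitPvalue:
    def test_deterministic_given_seed(self, rng):
        v = rng.normal(size=30)
        _, _, t = best_circular_split(v)
        params = CbsParams(n_perm=300, seed=11)
        assert split_pvalue(v, t, params) == split_pvalue(v, t, params)

    def test_overwhelming_step_reaches_minimal_p(self):
        v = np.concatenate([np.zeros(25), np.full(25, 10.0)])
        v += np.random.default_rng(3).normal(0, 1.0, size=50)
        _, _, t = best_circular_split(v)
        params = CbsParams(n_perm=500, seed=5)
        assert split_pvalue(v, t, params) <= 1 / (1 + 500) + 1e-12

    def test_noise_pvalues_roughly_uniform(self):
        # Monte-Carlo calibration: on pure noise the permutation p is a valid,
        # near-uniform p-value, so P(p < 0.05) should sit near 0.05
        hits = 0
        reps = 200
        params = CbsParams(n_perm=199, seed=77)
        gen = np.random.default_rng(42)
        for _ in range(reps):
            v = gen.normal(size=24)
            _, _, t = best_circular_split(v)
            p = split_pvalue(v, t, params, rng=np.random.default_rng(gen.integers(2**31)))
            hits += p < 0.05
        assert 0.01 <= hits / reps <= 0.12


class TestCbsSegment:
    def test_noiseless_step_recovers_two_segments(self):
        track = uniform_track(60)
        v = np.concatenate([np.zeros(30), np.ones(30)])
        profile = cbs_segment(track, v, CbsParams(n_perm=500, smooth=False), "s")
        assert [(s.n_features, s.seg_mean) for s in profile.segments] == [
            (30, 0.0),
            (30, 1.0),
        ]
        assert profile.bounds == [("chr1", 0, 30), ("chr1", 30, 60)]

    def test_constant_vector_single_segment(self):
        track = uniform_track(40)
        profile = cbs_segment(track, np.full(40, 0.3), CbsParams(n_perm=200), "s")
        assert len(profile.segments) == 1
        assert profile.segments[0].seg_mean == pytest.approx(0.3)

    def test_three_level_profile_recovered(self):
        track = uniform_track(120)
        gen = np.random.default_rng(9)
        truth = np.concatenate([np.zeros(40), np.full(40, 0.8), np.full(40, -0.8)])
        v = truth + gen.normal(0, 0.1, size=120)
        profile = cbs_segment(track, v, CbsParams(n_perm=2000, seed=4), "s")
        assert len(profile.segments) == 3
        breaks = [b[1] for b in profile.bounds[1:]]
        assert abs(breaks[0] - 40) <= 2 and abs(breaks[1] - 80) <= 2
        for seg, expected in zip(profile.segments, [0.0, 0.8, -0.8]):
            assert seg.seg_mean == pytest.approx(expected, abs=0.1)

    def test_segment_means_reconstruct_overall_mean(self, rng):
        # weighted mean of seg_means equals the mean of the input values
        track = uniform_track(80)
        v = rng.normal(0, 0.3, size=80)
        v[20:50] += 1.5
        profile = cbs_segment(track, v, CbsParams(n_perm=300, seed=1, smooth=False), "s")
        weighted = sum(s.seg_mean * s.n_features for s in profile.segments) / 80
        assert weighted == pytest.approx(v.mean(), abs=1e-12)
        for (chrom, lo, hi), seg in zip(profile.bounds, profile.segments):
            assert seg.seg_mean == pytest.approx(v[lo:hi].mean(), abs=1e-12)

    def test_shift_invariance_of_breakpoints(self, rng):
        track = uniform_track(60)
        v = rng.normal(0, 0.2, size=60)
        v[25:45] += 1.0
        params = CbsParams(n_perm=500, seed=6, smooth=False)
        base = cbs_segment(track, v, params, "s")
        shifted = cbs_segment(track, v + 5.0, params, "s")
        assert base.bounds == shifted.bounds
        for a, b in zip(base.segments, shifted.segments):
            assert b.seg_mean == pytest.approx(a.seg_mean + 5.0, abs=1e-9)

    def test_profile_independent_of_other_samples(self, rng):
        # same values + same sample id => identical result, regardless of
        # which other samples exist or in what order they are processed
        track = uniform_track(50)
        v = rng.normal(size=50)
        params = CbsParams(n_perm=300, seed=2)
        first = cbs_segment(track, v, params, "sampleA")
        again = cbs_segment(track, v, params, "sampleA")
        assert first.bounds == again.bounds
        np.testing.assert_array_equal(first.values, again.values)

    def test_two_chromosomes_segmented_independently(self):
        records = [("a%d" % i, "chr1", i * 10, i * 10 + 5) for i in range(20)]
        records += [("b%d" % i, "chr2", i * 10, i * 10 + 5) for i in range(20)]
        from cnage import FeatureTrack

        track = FeatureTrack.from_records(records, "cn_probe")
        v = np.concatenate([np.zeros(20), np.ones(20)])
        profile = cbs_segment(track, v, CbsParams(n_perm=200, smooth=False), "s")
        assert len(profile.segments) == 2
        assert [s.chrom for s in profile.segments] == ["chr1", "chr2"]
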