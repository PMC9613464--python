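"""Subclone detection: segmentation, projection, rank tests, thresholds."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsckit.cnv import (
    CNBinTrack,
    SegmentSet,
    call_gain_loss,
    compare_adjacent_segments,
    detect_subclonal_pattern,
    gain_pattern_from_means,
    project_segments,
    rank_sum_test,
    segment_track,
    stars,
)
from lsckit.simulate import CNSegmentSpec, simulate_cn_tracks


def make_track(values, bin_size=1000, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    starts = np.arange(len(values), dtype=np.int64) * bin_size
    return CNBinTrack(chrom, starts, starts + bin_size, values, bin_size)


def brute_force_ranksum_p(a, b):
    """Exact two-sided rank-sum p by enumerating all rank allocations."""
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1  # tie-free by construction
    n = len(a)
    obs = ranks[:n].sum()
    null = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    null = np.asarray(null)
    mean = null.mean()
    # two-sided: as or more extreme in |W - E[W]|
    return float((np.abs(null - mean) >= abs(obs - mean) - 1e-9).mean())


class TestSegmentation:
    def test_constant_track_single_segment(self):
        seg = segment_track(make_track(np.full(500, 2.0)))
        assert len(seg) == 1

    def test_clean_step_found_exactly(self):
        track = make_track(np.r_[np.full(2000, 2.0), np.full(2000, 4.0)])
        seg = segment_track(track)
        assert len(seg) == 2
        assert seg.ends[0] == 2000 * 1000
        # oracle: exhaustive single-changepoint Gaussian cost
        x = track.cn
        costs = []
        for k in range(1, len(x)):
            l, r = x[:k], x[k:]
            costs.append(((l - l.mean()) ** 2).sum() + ((r - r.mean()) ** 2).sum())
        assert int(np.argmin(costs)) + 1 == 2000

    def test_subthreshold_step_not_split(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2.0, 1.0, 4000)
        x[2000:] += 0.1
        seg = segment_track(make_track(x), penalty=200.0)
        assert len(seg) == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            segment_track(make_track([2.0]))


class TestProjection:
    def test_single_segment_holds_all_bins(self):
        track = make_track([2.0, 2.1, 1.9, 2.0])
        seg = SegmentSet("chr1", np.array([0]), np.array([4000]), ("1",))
        proj, excluded = project_segments(seg, track)
        assert excluded == 0
        assert len(proj[0][3]) == 4

    def test_midpoint_assignment(self):
        track = make_track([1.0, 2.0, 3.0, 4.0, 5.0])
        seg = SegmentSet(
            "chr1", np.array([0, 1000, 3000]), np.array([1000, 3000, 5000]),
            ("a", "b", "c"),
        )
        proj, _ = project_segments(seg, track)
        assert [list(v) for *_x, v in proj] == [[1.0], [2.0, 3.0], [4.0, 5.0]]

    def test_bin_count_conserved_with_exclusions(self):
        track = make_track(np.arange(10, dtype=float))
        seg = SegmentSet("chr1", np.array([2000]), np.array([7000]), ("mid",))
        with pytest.warns(UserWarning, match="outside"):
            proj, excluded = project_segments(seg, track)
        assert sum(len(v) for *_x, v in proj) + excluded == 10

    def test_chromosome_mismatch(self):
        track = make_track([1.0, 2.0], chrom="chr2")
        seg = SegmentSet("chr1", np.array([0]), np.array([2000]), ("1",))
        with pytest.raises(ValueError, match="mismatch"):
            project_segments(seg, track)


class TestRankSum:
    def test_worked_example_exact_tenth(self):
        _, p = rank_sum_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_all_ties_p_one(self):
        _, p = rank_sum_test(np.full(10, 2.0), np.full(12, 2.0))
        assert p == 1.0

    @given(
        st.integers(2, 8),
        st.integers(2, 8),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_p_matches_enumeration(self, n, m, rnd):
        vals = rnd.sample(range(1000), n + m)
        a = np.asarray(vals[:n], float)
        b = np.asarray(vals[n:], float)
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    def test_stars_thresholds(self):
        assert stars(0.2) == "ns"
        assert stars(0.0387516) == "*"
        assert stars(0.004922) == "**"   # the printed donor-vs-culture pair
        assert stars(3.96e-09) == "***"


class TestAdjacentComparisons:
    def test_pairs_and_direction(self):
        rng = np.random.default_rng(0)
        proj = [
            ("1", 0, 1000, rng.normal(2.0, 0.1, 50)),
            ("2", 1000, 2000, rng.normal(3.0, 0.1, 50)),
            ("3", 2000, 3000, rng.normal(2.0, 0.1, 50)),
        ]
        comps = compare_adjacent_segments(proj)
        assert [c.pair for c in comps] == ["1 to 2", "2 to 3"]
        assert [c.direction for c in comps] == [1, -1]
        assert all(c.p_value < 0.001 for c in comps)

    def test_empty_segment_skipped_with_warning(self):
        proj = [
            ("1", 0, 1000, np.arange(30.0)),
            ("2", 1000, 2000, np.array([])),
            ("3", 2000, 3000, np.arange(30.0) + 50),
        ]
        with pytest.warns(UserWarning, match="skipped"):
            comps = compare_adjacent_segments(proj)
        assert [c.pair for c in comps] == ["1 to 3"]


class TestPatternDetection:
    @staticmethod
    def run_once(phi, seed, noise=0.3, bins=500):
        profile = [
            CNSegmentSpec(i * bins * 1000, (i + 1) * bins * 1000,
                          base_cn=2.0, subclone_cn=5.0 if i % 2 else 2.0,
                          phi=phi, noise_sd=noise)
            for i in range(6)
        ]
        ref, query = simulate_cn_tracks(profile, seed=seed)
        seg = SegmentSet(
            "chrS",
            np.array([s.start for s in profile]),
            np.array([s.end for s in profile]),
            tuple(str(i + 1) for i in range(6)),
        )
        ref_proj, _ = project_segments(seg, ref)
        pattern = gain_pattern_from_means([float(np.mean(v)) for *_x, v in ref_proj])
        proj, _ = project_segments(seg, query)
        return detect_subclonal_pattern(compare_adjacent_segments(proj), pattern)

    def test_pure_clone_detected(self):
        res = self.run_once(phi=1.0, seed=2)
        assert res["verdict"] == "detected"
        assert res["concordance"] == 1.0

    def test_null_not_detected(self):
        res = self.run_once(phi=0.0, seed=2)
        assert res["verdict"] == "not_detected"

    def test_power_nondecreasing_in_phi(self):
        rates = []
        for phi in (0.0, 0.1, 0.3, 0.5):
            hits = sum(
                self.run_once(phi, seed, bins=100)["verdict"] == "detected"
                for seed in range(10)
            )
            rates.append(hits)
        assert rates == sorted(rates)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            detect_subclonal_pattern([], ["up"])


class TestGainLoss:
    def test_thresholds_and_boundaries(self, chr11q_segments):
        seg = SegmentSet(
            "chr11",
            np.array([r[1] for r in chr11q_segments[:5]]),
            np.array([r[2] for r in chr11q_segments[:5]]),
            tuple(r[3] for r in chr11q_segments[:5]),
        )
        calls = call_gain_loss(seg, [1.49, 1.5, 2.0, 2.5, 2.51])
        assert [c.call for c in calls] == ["loss", "neutral", "neutral", "neutral", "gain"]

    def test_table3_fixture_contiguous(self, chr11q_segments):
        # the printed reference segments tile chr11q without gaps
        for a, b in zip(chr11q_segments[:-1], chr11q_segments[1:]):
            assert a[2] == b[1]
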