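"""CORE calling, cataloging, detection and predictability ranking."""

import numpy as np
import pytest

from lsckit.cores import (
    CORE,
    CRESet,
    build_catalog,
    call_cores,
    cre_accessibility_frequency,
    detection_matrix,
    rank_predictability,
)
from lsckit.simulate import PlantedCore, SimConfig, simulate_peak_atlas


def peak_set(starts, width=200, chrom="chr1", sample="s", group="NA"):
    return CRESet(sample, group, tuple((chrom, int(s), int(s) + width) for s in starts))


class TestCallCores:
    def test_empty_and_below_min_order(self):
        assert call_cores(CRESet("s", "NA", ())) == []
        assert call_cores(peak_set([100])) == []

    def test_tight_cluster_among_sparse_background(self):
        """Only the planted 7-peak run survives the uniform-null span test."""
        rng = np.random.default_rng(7)
        bg = rng.integers(0, 100_000_000, 220)
        bg = bg[(bg < 19_000_000) | (bg > 21_000_000)]
        planted = [20_000_000 + i * 2200 for i in range(7)]
        cres = peak_set(list(bg) + planted)
        cores = call_cores(cres)
        assert len(cores) == 1
        assert cores[0].order == 7
        assert cores[0].start == planted[0]
        assert cores[0].end == planted[-1] + 200
        # brute-force cross-check: no accepted-core-free run of any order is
        # tighter than its Bonferroni-corrected uniform-null quantile
        from scipy import stats

        starts = np.array(sorted([*bg, *planted]))
        extent = starts[-1] + 200 - starts[0]
        n = len(starts)
        for k in range(2, 21):
            spans = starts[k - 1:] - starts[: n - k + 1]
            p = stats.beta.cdf(spans / extent, k - 1, n - k + 2)
            hits = np.flatnonzero(p <= 0.05 / len(spans))
            for i in hits:  # every qualifying run lies inside the called CORE
                assert starts[i] >= planted[0] and starts[i + k - 1] <= planted[-1]

    def test_two_separated_clusters_not_swallowed(self):
        """A high-order window containing two tight clusters must not merge them."""
        rng = np.random.default_rng(3)
        bg = list(rng.integers(0, 10_000_000, 60))
        c1 = [1_000_000 + i * 2000 for i in range(7)]
        c2 = [1_500_000 + i * 2000 for i in range(7)]
        cores = call_cores(peak_set(bg + c1 + c2))
        tight = [c for c in cores if c.end - c.start < 50_000]
        assert len(tight) == 2
        assert {c.start for c in tight} == {c1[0], c2[0]}

    def test_called_cores_non_overlapping(self):
        rng = np.random.default_rng(11)
        starts = list(rng.integers(0, 5_000_000, 80)) + [
            2_000_000 + i * 1500 for i in range(9)
        ]
        cores = call_cores(peak_set(starts))
        cores = sorted(cores, key=lambda c: c.start)
        for a, b in zip(cores[:-1], cores[1:]):
            assert a.end <= b.start

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        starts = list(rng.integers(0, 5_000_000, 50)) + [
            700_000 + i * 1000 for i in range(6)
        ]
        shuffled = starts.copy()
        rng.shuffle(shuffled)
        assert call_cores(peak_set(starts)) == call_cores(peak_set(shuffled))

    def test_unsorted_input_rejected_at_construction(self):
        with pytest.raises(ValueError):
            CRESet("s", "NA", (("chr1", 100, 50),))

    def test_name_renders_one_based(self):
        core = CORE("chr9", 2014810, 2032652, ((2014810, 2015000), (2032000, 2032652)))
        assert core.name == "CORE-chr9-2014811-2032652"


class TestCatalog:
    def c(self, chrom, start, end):
        return CORE(chrom, start, end, ((start, start + 10), (end - 10, end)))

    def test_identical_cores_merge_once(self):
        cat = build_catalog({"a": [self.c("chr1", 0, 1000)], "b": [self.c("chr1", 0, 1000)]})
        assert len(cat) == 1
        assert cat[0].contributors == {"a", "b"}

    def test_chaining_merge(self):
        cat = build_catalog({"a": [self.c("chr1", 0, 10_000)],
                             "b": [self.c("chr1", 9_000, 20_000)]})
        assert len(cat) == 1
        assert (cat[0].start, cat[0].end) == (0, 20_000)

    def test_different_chromosomes_stay_separate(self):
        cat = build_catalog({"a": [self.c("chr1", 0, 1000), self.c("chr2", 0, 1000)]})
        assert len(cat) == 2


class TestDetectionAndPC:
    def build(self, presence_pos=1.0, presence_neg=0.0, seed=0):
        cfg = SimConfig(
            seed=seed,
            n_lsc_pos=10,
            n_lsc_neg=10,
            background_peak_rate=3.0,
            planted_cores=(PlantedCore(start=1_000_000,
                                       presence_prob_pos=presence_pos,
                                       presence_prob_neg=presence_neg),),
        )
        atlas, groups = simulate_peak_atlas(cfg)
        per = {s: call_cores(c) for s, c in atlas.items()}
        return atlas, groups, per

    def test_degenerate_presence_frequencies(self):
        """Cluster carried by every LSC+ and no LSC- sample: frequencies 1/0, PC 1.

        Every sample shares an identical sparse regular background grid (no
        run of which is unexpectedly tight), so the catalog holds exactly
        the planted cluster.
        """
        grid = list(range(3_000_000, 60_000_000, 500_000))
        cluster = [1_000_000 + i * 2000 for i in range(7)]
        groups, per = {}, {}
        for i in range(10):
            s = f"s{i}"
            groups[s] = "LSC+" if i < 5 else "LSC-"
            starts = grid + cluster if i < 5 else grid
            per[s] = call_cores(peak_set(starts, sample=s, group=groups[s]))
        cat = build_catalog(per)
        assert len(cat) == 1
        assert cat[0].start == cluster[0]
        dm = detection_matrix(cat, per, groups)
        res = rank_predictability(dm)[0]
        assert (res.freq_pos, res.freq_neg, res.pc, res.rank) == (1.0, 0.0, 1.0, 1)

    def test_contributor_always_detected(self):
        _, groups, per = self.build(1.0, 1.0)
        cat = build_catalog(per)
        dm = detection_matrix(cat, per, groups)
        for i, entry in enumerate(cat):
            for sample in entry.contributors:
                assert dm.matrix[i, dm.samples.index(sample)]

    def test_uninformative_core_pc_half(self):
        _, groups, per = self.build(1.0, 1.0)
        cat = build_catalog(per)
        dm = detection_matrix(cat, per, groups)
        res = {r.core_name: r for r in rank_predictability(dm)}
        planted = [e for e in cat if e.start < 1_013_000 and e.end > 1_000_000][0]
        assert res[planted.name].pc == 0.5

    def test_pc_arithmetic(self):
        # 31/41 detected in LSC+, 10/52 in LSC-
        groups = {f"p{i}": "LSC+" for i in range(41)} | {f"n{i}": "LSC-" for i in range(52)}
        core = CORE("chr9", 0, 100, ((0, 50), (60, 100)))
        per = {s: [] for s in groups}
        for i in range(31):
            per[f"p{i}"] = [core]
        for i in range(10):
            per[f"n{i}"] = [core]
        cat = build_catalog(per)
        dm = detection_matrix(cat, per, groups)
        res = rank_predictability(dm)[0]
        assert res.pc == pytest.approx((31 / 41 + (1 - 10 / 52)) / 2)
        assert res.pc == pytest.approx(0.7819, abs=5e-4)

    def test_empty_group_rejected(self):
        groups = {"a": "LSC+"}
        core = CORE("chr1", 0, 100, ((0, 40), (50, 100)))
        dm = detection_matrix(build_catalog({"a": [core]}), {"a": [core]}, groups)
        with pytest.raises(ValueError, match="non-empty"):
            rank_predictability(dm)

    def test_pc_bounds_property(self):
        _, groups, per = self.build(0.7, 0.3, seed=5)
        cat = build_catalog(per)
        res = rank_predictability(detection_matrix(cat, per, groups))
        assert all(0.0 <= r.pc <= 1.0 for r in res)
        for r in res:
            if r.freq_pos == r.freq_neg:
                assert r.pc == 0.5


class TestCreAccessibility:
    def test_ubiquitous_and_absent_cres(self):
        member_starts = [1000, 3000]
        cres = {}
        groups = {}
        per = {}
        core = CORE("chr1", 1000, 3200, ((1000, 1200), (3000, 3200)))
        for i in range(6):
            s = f"s{i}"
            groups[s] = "LSC+" if i < 3 else "LSC-"
            cres[s] = peak_set(member_starts, sample=s, group=groups[s])
            per[s] = [core]
        cat = build_catalog(per)
        rows = cre_accessibility_frequency(cat[0], per, cres, groups)
        assert len(rows) == 2
        for row in rows:
            assert row["frac_LSC+"] == 1.0
            assert row["frac_LSC-"] == 1.0

    def test_group_specific_fraction(self):
        core = CORE("chr1", 1000, 3200, ((1000, 1200), (3000, 3200)))
        groups = {"a": "LSC+", "b": "LSC-"}
        cres = {
            "a": peak_set([1000, 3000], sample="a"),
            "b": peak_set([500_000], sample="b"),  # no overlap with members
        }
        per = {"a": [core], "b": []}
        cat = build_catalog(per)
        rows = cre_accessibility_frequency(cat[0], per, cres, groups)
        for row in rows:
            assert row["frac_LSC+"] == 1.0
            assert row["frac_LSC-"] == 0.0
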