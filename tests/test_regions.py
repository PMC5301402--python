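"""Region calling: ranking, peak extension, merging, intersection, recovery."""

import numpy as np
import pytest

from vgrscan.regions import (Region, RegionParams, VGR, call_regions,
                             intersect_region_sets, rank_scores, recovery_score)
from vgrscan.stats import AssocTrack

from oracles import call_regions_reference, rank_reference


def make_track(values, chroms=None, positions=None, statistic="fst"):
    values = np.asarray(values, dtype=float)
    n = values.size
    chroms = np.asarray(chroms if chroms is not None else ["1"] * n, dtype=object)
    positions = np.asarray(positions if positions is not None
                           else np.arange(1, n + 1) * 1_000_000, dtype=np.int64)
    ids = np.array([f"m{i}" for i in range(n)], dtype=object)
    return AssocTrack(ids, chroms, positions, statistic, values)


class TestRankScores:
    def test_strictly_decreasing_vector(self):
        v = np.arange(10, 0, -1, dtype=float)
        np.testing.assert_array_equal(rank_scores(v, "desc"), np.arange(1, 11))

    def test_tie_goes_to_earlier_position(self):
        ranks = rank_scores(np.array([0.3, 0.5, 0.5, 0.1]), "desc")
        assert ranks[1] == 1 and ranks[2] == 2

    def test_nan_excluded(self):
        ranks = rank_scores(np.array([0.2, np.nan, 0.4]), "desc")
        assert np.isnan(ranks[1]) and ranks[2] == 1 and ranks[0] == 2

    def test_all_nan_raises(self):
        with pytest.raises(ValueError):
            rank_scores(np.array([np.nan, np.nan]), "desc")

    @pytest.mark.parametrize("direction", ["asc", "desc"])
    def test_matches_quadratic_oracle(self, direction):
        rng = np.random.default_rng(8)
        for _ in range(25):
            v = rng.choice([0.1, 0.2, 0.3, 0.7, np.nan], size=rng.integers(2, 40))
            if not np.isfinite(v).any():
                continue
            np.testing.assert_array_equal(rank_scores(v, direction),
                                          rank_reference(v, direction))


class TestCallRegions:
    def test_isolated_top_snp_gives_point_region(self):
        # one extreme marker far from every secondary marker
        v = [0.9, 0.1, 0.12, 0.11]
        track = make_track(v, positions=[1_000_000, 50_000_000, 60_000_000, 70_000_000])
        regions = call_regions(track, RegionParams(n_top=1, secondary_fraction=0.25,
                                                   window_bp=1_500_000))
        assert len(regions) == 1
        assert regions[0].start_bp == regions[0].end_bp == 1_000_000

    def test_clustered_top_snps_merge_to_one_region(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 4_000_000, 1000), 50, replace=False))
        v = rng.uniform(0.5, 1.0, size=50)
        track = make_track(v, positions=pos)
        regions = call_regions(track, RegionParams(n_top=50, secondary_fraction=1.0,
                                                   window_bp=1_500_000))
        assert len(regions) == 1

    def test_ten_marker_toy_against_exhaustive_rule(self):
        scores = np.array([9, 1, 2, 8, 3, 4, 10, 5, 6, 7], dtype=float)
        pos = np.arange(1, 11) * 1_000_000
        track = make_track(scores, positions=pos)
        params = RegionParams(n_top=2, secondary_fraction=0.5, window_bp=3_000_000)
        regions = call_regions(track, params)
        expected = call_regions_reference(["1"] * 10, pos, scores, 2, 0.5,
                                          3_000_000, "desc")
        assert [(r.chrom, r.start_bp, r.end_bp) for r in regions] == \
               [(c, s, e) for c, s, e, *_ in expected]

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(77)
        for _ in range(120):
            n = int(rng.integers(5, 50))
            chroms = sorted(rng.choice(["1", "2"], size=n))
            positions = np.zeros(n, dtype=np.int64)
            for c in set(chroms):
                mask = np.array(chroms) == c
                positions[mask] = np.sort(rng.choice(
                    np.arange(1, 20_000_000, 1000), mask.sum(), replace=False))
            values = rng.uniform(size=n).round(2)  # rounding forces ties
            track = make_track(values, chroms=chroms, positions=positions)
            n_top = int(rng.integers(1, 6))
            frac = float(rng.uniform(0.1, 0.9))
            window = int(rng.choice([500_000, 2_000_000, 8_000_000]))
            got = call_regions(track, RegionParams(n_top, frac, window))
            exp = call_regions_reference(chroms, positions, values, n_top, frac,
                                         window, "desc")
            assert [(r.chrom, r.start_bp, r.end_bp, r.peak_marker_id)
                    for r in got] == \
                   [(c, s, e, f"m{peak}") for c, s, e, peak, _ in exp]
            assert [sorted(r.member_marker_ids) for r in got] == \
                   [sorted(f"m{i}" for i in mem) for *_, mem in exp]

    def test_fewer_markers_than_n_top_warns(self):
        track = make_track([0.5, 0.4, 0.3])
        with pytest.warns(UserWarning, match="n_top"):
            regions = call_regions(track, RegionParams(n_top=50,
                                                       secondary_fraction=1.0,
                                                       window_bp=10_000_000))
        assert len(regions) == 1

    def test_window_monotonicity(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(np.arange(1, 50_000_000, 1000), 40, replace=False))
        track = make_track(rng.uniform(size=40), positions=pos)
        prev_spans, prev_count = None, None
        for window in (0, 1_000_000, 5_000_000, 20_000_000):
            regions = call_regions(track, RegionParams(5, 0.5, window))
            span = sum(r.end_bp - r.start_bp for r in regions)
            if prev_spans is not None:
                assert span >= prev_spans
                assert len(regions) <= prev_count
            prev_spans, prev_count = span, len(regions)

    def test_members_come_from_top_tiers(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(size=60)
        track = make_track(v, positions=np.arange(1, 61) * 200_000)
        params = RegionParams(n_top=4, secondary_fraction=0.2, window_bp=1_000_000)
        ranks = rank_scores(v, "desc")
        t2 = set(np.flatnonzero(ranks <= np.ceil(0.2 * 60)))
        for r in call_regions(track, params):
            idx = {int(m[1:]) for m in r.member_marker_ids}
            assert any(ranks[i] <= 4 for i in idx)  # at least one T1 anchor
            assert idx <= (t2 | {i for i in idx if ranks[i] <= 4})


class TestIntersect:
    @staticmethod
    def region(chrom, start, end, peak_pos=None, value=0.5):
        peak_pos = peak_pos if peak_pos is not None else start
        return Region(chrom, start, end, f"p{start}", peak_pos, value, [])

    def test_identical_lists(self):
        a = [self.region("1", 100, 200), self.region("2", 5, 5)]
        vgrs = intersect_region_sets(a, a)
        assert len(vgrs) == 2
        assert vgrs[0].fst_peak == vgrs[0].emmax_peak

    def test_disjoint_lists_empty(self):
        a = [self.region("1", 100, 200)]
        b = [self.region("1", 300, 400), self.region("2", 100, 200)]
        assert intersect_region_sets(a, b) == []

    def test_partial_overlap_unions_span(self):
        a = [self.region("3", 10_000_000, 12_000_000)]
        b = [self.region("3", 11_500_000, 13_000_000)]
        (v,) = intersect_region_sets(a, b)
        assert (v.start_bp, v.end_bp) == (10_000_000, 13_000_000)
        assert v.fst_peak and v.emmax_peak

    def test_symmetric_up_to_peak_labels(self):
        rng = np.random.default_rng(10)
        a = [self.region("1", s, s + 500) for s in rng.choice(range(0, 10_000, 1500), 4,
                                                              replace=False) + 1]
        b = [self.region("1", s, s + 700) for s in rng.choice(range(0, 10_000, 1700), 4,
                                                              replace=False) + 1]
        v1 = intersect_region_sets(a, b)
        v2 = intersect_region_sets(b, a)
        assert [(v.chrom, v.start_bp, v.end_bp) for v in v1] == \
               [(v.chrom, v.start_bp, v.end_bp) for v in v2]

    def test_chained_component_unified(self):
        # fst1 - emmax - fst2 chain collapses to one VGR spanning all three
        a = [self.region("1", 100, 200, value=0.6),
             self.region("1", 300, 400, value=0.7)]
        b = [self.region("1", 150, 350, value=1e-8)]
        (v,) = intersect_region_sets(a, b)
        assert (v.start_bp, v.end_bp) == (100, 400)
        assert v.fst_peak[1] == 0.7  # larger theta wins

    def test_point_region_touching_interval(self):
        a = [self.region("1", 500, 500)]
        b = [self.region("1", 500, 900)]
        assert len(intersect_region_sets(a, b)) == 1


class TestRecovery:
    def test_perfect_recovery(self):
        truth = [("1", 100, 200), ("2", 50, 80)]
        vgrs = [VGR(1, "1", 100, 200, fst_peak=(150, 0.9)),
                VGR(2, "2", 50, 80, fst_peak=(60, 0.8))]
        assert recovery_score(vgrs, truth) == (1.0, 0)

    def test_empty_calls(self):
        sens, fp = recovery_score([], [("1", 100, 200)])
        assert sens == 0.0 and fp == 0

    def test_slack_rescues_near_miss_and_flags_stray(self):
        truth = [("1", 1_000_000, 2_000_000)]
        vgrs = [VGR(1, "1", 2_400_000, 2_500_000, fst_peak=(2_450_000, 0.9)),
                VGR(2, "9", 5_000_000, 5_000_000, fst_peak=(5_000_000, 0.7))]
        assert recovery_score(vgrs, truth, slack_bp=0) == (0.0, 2)
        assert recovery_score(vgrs, truth, slack_bp=500_000) == (1.0, 1)
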