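"""Tracking, the change-ratio degenerate rules, and arm-level summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from retquant import longitudinal as lng
from retquant import morphometry as mm


def make_track(heights: dict, arm="injected", track_id="t0") -> lng.DruseTrack:
    tr = lng.DruseTrack(
        track_id=track_id,
        eye_id="E",
        arm=arm,
        anchor=(5.0, 5.0),
        anchor_footprint=np.array([[5, 5]]),
    )
    for t, h in heights.items():
        tr.records[t] = lng.TrackRecord(height=h, visible=h > 0, detected=h > 0)
    return tr


class TestChangeRatio:
    def test_unchanged_druse_has_ratio_one(self):
        tr = make_track({0: 25.0, 6: 25.0})
        assert lng.change_ratio(tr, 6).ratio == pytest.approx(1.0)

    def test_zero_baseline_sets_denominator_to_one(self):
        """A druse that appeared during the study: ratio is the height itself."""
        tr = make_track({0: 0.0, 6: 12.0})
        assert lng.change_ratio(tr, 6).ratio == pytest.approx(12.0)

    def test_disappeared_druse_has_ratio_zero(self):
        tr = make_track({0: 20.0, 6: 0.0})
        assert lng.change_ratio(tr, 6).ratio == 0.0

    def test_absent_at_both_visits_is_zero(self):
        tr = make_track({0: 0.0, 3: 0.0, 6: 9.0})
        assert lng.change_ratio(tr, 3).ratio == 0.0

    @pytest.mark.parametrize("h0,ht", list(itertools.product([0.0, 0.5, 7.0, 31.0], repeat=2)))
    def test_ratio_axioms(self, h0, ht):
        tr = make_track({0: h0, 3: ht})
        r = lng.change_ratio(tr, 3).ratio
        assert r >= 0
        assert lng.change_ratio(tr, 0).ratio == (1.0 if h0 > 0 else 0.0)


def flat_tmaps(timepoints, shape=(12, 40)):
    return {t: mm.ThicknessMap(np.full(shape, 30.0)) for t in timepoints}


def detection(centroid, height=20.0, visible=True):
    b, a = int(round(centroid[0])), int(round(centroid[1]))
    return mm.DruseMeasurement(
        druse_id=f"d{b}_{a}",
        footprint=np.array([[b, a - 1], [b, a], [b, a + 1], [b + 1, a]]),
        sections=[b, b + 1],
        average_height=height,
        visible=visible,
        centroid=(float(b), float(a)),
    )


class TestBuildTracks:
    def test_identical_detections_link_one_to_one(self):
        dets = {0: [detection((3, 10)), detection((8, 30))], 3: [detection((3, 10)), detection((8, 30))]}
        tracks = lng.build_tracks(dets, flat_tmaps([0, 3]), eye_id="E", arm="injected")
        assert len(tracks) == 2
        assert all(tr.records[0].detected and tr.records[3].detected for tr in tracks)

    def test_transient_druse_is_measured_at_every_visit(self):
        dets = {0: [], 3: [detection((5, 20))], 6: []}
        tracks = lng.build_tracks(dets, flat_tmaps([0, 3, 6]), eye_id="E", arm="injected")
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.records[3].detected and not tr.records[0].detected
        assert tr.records[0].height == 0.0  # flat map: nothing at the anchor
        assert tr.records[6].height == 0.0
        assert not tr.records[0].visible

    def test_greedy_matches_exhaustive_assignment_on_small_instance(self):
        """Distances straddling the radius: compare to brute-force matching."""
        t0 = [detection((2, 5)), detection((6, 20)), detection((10, 35))]
        t1 = [detection((2, 6)), detection((6, 33)), detection((10, 36))]
        tmaps = flat_tmaps([0, 3], shape=(12, 40))
        spacing = np.array([tmaps[0].bscan_spacing, tmaps[0].ascan_spacing])
        radius = 200.0
        tracks = lng.build_tracks({0: t0, 3: t1}, tmaps, match_radius=radius)
        got_links = set()
        for tr in tracks:
            if tr.records[0].detected and tr.records[3].detected:
                got_links.add(tuple(int(x) for x in np.array(tr.anchor)))
        # brute force: best assignment over all injective partial matchings
        def cost(pairs):
            return sum(np.linalg.norm((np.array(a.centroid) - np.array(b.centroid)) * spacing) for a, b in pairs)

        best, best_cost = set(), np.inf
        for k in range(len(t1) + 1):
            for subset in itertools.combinations(range(len(t1)), k):
                for perm in itertools.permutations(range(len(t0)), k):
                    pairs = [(t0[i], t1[j]) for i, j in zip(perm, subset)]
                    if any(
                        np.linalg.norm((np.array(a.centroid) - np.array(b.centroid)) * spacing) > radius
                        for a, b in pairs
                    ):
                        continue
                    c = cost(pairs) - 1e6 * k  # prefer more links, then shorter
                    if c < best_cost:
                        best_cost, best = c, {tuple(int(x) for x in np.array(a.centroid)) for a, _ in pairs}
        assert got_links == best

    def test_missing_thickness_map_is_an_error(self):
        with pytest.raises(ValueError, match="thickness map"):
            lng.build_tracks({0: [], 3: []}, flat_tmaps([0]))


class TestArmSummaries:
    def test_no_tracks_counts_zero(self):
        assert lng.count_visible([], 0, "injected") == 0

    def test_unknown_arm_is_an_error(self):
        with pytest.raises(ValueError, match="unknown arm"):
            lng.count_visible([make_track({0: 10.0})], 0, "sham")

    def test_published_injected_series_increment(self):
        """The injected-eye count series rises by seven drusen from 9 to 12 months."""
        s = lng.INJECTED_EYE_DRUSEN_COUNTS
        assert s[12] - s[9] == 7
        assert s[0] == 25

    def test_count_matches_truth_catalog(self):
        """Noise-free study: visible count equals the seeded druse count."""
        from retquant import synthetic as syn

        boundaries, truth = syn.generate_two_arm_study(
            syn.OctStudySpec(axial_noise_sd=0.0, timepoints=(0, 3)),
            n_drusen_per_arm=8,
            seed=5,
        )
        volumes = [
            mm.BoundaryVolume.from_dataframe(sub)
            for _, sub in boundaries.groupby(["eye_id", "timepoint_months"])
        ]
        tracks = lng.track_study(volumes)
        base = truth[(truth.timepoint_months == 0) & (truth.amplitude_um > 0)]
        for arm, eyes in (("injected", ("A_OS", "B_OS")), ("uninjected", ("A_OD", "B_OD"))):
            expected = int(base.eye_id.isin(eyes).sum())
            assert lng.count_visible(tracks, 0, arm) == expected == 8

    def test_unchanged_heights_give_zero_change(self):
        tracks = [make_track({0: 20.0, 3: 20.0}), make_track({0: 10.0, 3: 10.0}, track_id="t1")]
        assert lng.average_height_change(tracks, 3, "injected") == 0.0

    def test_height_change_arithmetic(self):
        tracks = [make_track({0: 20.0, 3: 25.0})]
        assert lng.average_height_change(tracks, 3, "injected") == pytest.approx(5.0)

    def test_empty_arm_is_an_error(self):
        with pytest.raises(ValueError):
            lng.average_height_change([], 3, "injected")


class TestSummarize:
    def test_single_unchanged_track(self):
        df = lng.summarize([make_track({0: 25.0, 3: 25.0})])
        row = df[df.timepoint_months == 3].iloc[0]
        assert row.mean_ratio == pytest.approx(1.0)
        assert row.n_ratio_eq1 == 1 and row.n_ratio_gt1 == 0

    def test_zero_and_doubling_tracks(self):
        tracks = [
            make_track({0: 20.0, 3: 0.0}, track_id="a"),
            make_track({0: 15.0, 3: 30.0}, track_id="b"),
        ]
        row = lng.summarize(tracks)[lambda d: d.timepoint_months == 3].iloc[0]
        assert row.mean_ratio == pytest.approx(1.0)
        assert row.n_ratio_eq0 == 1 and row.n_ratio_gt1 == 1

    def test_count_conservation_identity(self, ten_seed_studies):
        """Visible count = persisting-from-baseline + newly visible, per arm."""
        tracks = ten_seed_studies[0]
        for arm in ("injected", "uninjected"):
            arm_tracks = [tr for tr in tracks if tr.arm == arm]
            for t in (3, 6, 9, 12):
                persisting = sum(
                    1 for tr in arm_tracks if tr.records[0].visible and tr.records[t].visible
                )
                new = sum(
                    1 for tr in arm_tracks if not tr.records[0].visible and tr.records[t].visible
                )
                assert lng.count_visible(tracks, t, arm) == persisting + new

    def test_treated_arm_ratio_below_untreated(self, ten_seed_studies):
        """Growth-suppressed arm shows smaller mean ratios at 3 and 6 months."""
        df = lng.summarize(ten_seed_studies[0])
        for t in (3, 6):
            sub = df[df.timepoint_months == t].set_index("arm")
            assert sub.loc["injected", "mean_ratio"] < sub.loc["uninjected", "mean_ratio"]


class TestEffectDirection:
    def test_treated_height_change_below_untreated_in_most_seeds(self, ten_seed_studies):
        wins = 0
        for tracks in ten_seed_studies:
            ordered = all(
                lng.average_height_change(tracks, t, "injected")
                < lng.average_height_change(tracks, t, "uninjected")
                for t in (3, 6)
            )
            wins += ordered
        assert wins >= 9

    def test_shuffling_arm_labels_destroys_the_ordering(self, ten_seed_studies):
        """Permuted labels: the treated/untreated split is no longer one-sided."""
        rng = np.random.default_rng(2024)
        wins = 0
        for tracks in ten_seed_studies:
            labels = [tr.arm for tr in tracks]
            perm = rng.permutation(labels)
            heights = {"injected": {3: [], 6: [], 0: []}, "uninjected": {3: [], 6: [], 0: []}}
            for tr, arm in zip(tracks, perm):
                for t in (0, 3, 6):
                    heights[arm][t].append(tr.height(t))
            def change(arm, t):
                return np.mean(heights[arm][t]) - np.mean(heights[arm][0])
            wins += all(change("injected", t) < change("uninjected", t) for t in (3, 6))
        # two-sided sign test at p=0.5 must not reject randomness
        p = sps.binomtest(wins, 10, 0.5).pvalue
        assert p > 0.05
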