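from __future__ import annotations

import random

import pytest

from coasttrack.detections_io import Detection, Receiver
from coasttrack.geo_solar import GeoPoint, great_circle_distance, sun_events
from coasttrack.segmentation import (
    Segment,
    SegmentationConfig,
    SegmentLabel,
    along_track_stopover_days,
    classify_segments,
    daily_mean_speed,
    days_at_study_area,
    detection_labels,
    flight_start_phase,
    initial_stopover,
)
from coasttrack.track_builder import Track, transitions

from conftest import dt, make_track, random_small_track

CFG = SegmentationConfig()


class TestConfig:
    def test_defaults_match_published_thresholds(self):
        assert CFG.initial_radius_km == 20
        assert CFG.cluster_radius_km == 2.6
        assert CFG.stop_dwell_min_h == 1
        assert CFG.flight_speed_min_mps == 5
        assert CFG.flight_speed_max_mps == 26
        assert CFG.short_visit_max_min == 35
        assert CFG.stop_gap_max_days == 3
        assert CFG.stop_dist_max_km == 32

    def test_speed_boundary_consistency_enforced(self):
        with pytest.raises(ValueError):
            SegmentationConfig(flight_speed_min_mps=4.0)


class TestInitialStopover:
    def test_basic_duration(self, grid_registry, deployment):
        # release at G00 (same location); outside-cluster detection at +2.5 d
        track = make_track(
            deployment, [(1, "G00"), (24, "G00"), (48, "G00"), (60, "G11")]
        )
        res = initial_stopover(track, grid_registry, CFG)
        assert res is not None
        assert res.duration_days == pytest.approx(2.5)
        assert not res.minimum_estimate
        assert res.end_index == 3

    def test_never_outside_is_minimum_estimate(self, grid_registry, deployment):
        track = make_track(deployment, [(1, "G00"), (96, "G00")])
        res = initial_stopover(track, grid_registry, CFG)
        assert res.minimum_estimate
        assert res.duration_days == pytest.approx(4.0)
        assert res.end_index == len(track.detections)

    def test_first_detection_far_away_absent(self, grid_registry, deployment):
        # G24 is ~ 47 km from the release site: no initial stopover
        assert (
            great_circle_distance(
                deployment.release_site, grid_registry["G24"].location
            )
            > 20
        )
        track = make_track(deployment, [(1, "G24"), (10, "G23")])
        assert initial_stopover(track, grid_registry, CFG) is None

    def test_invariant_to_later_detections(self, grid_registry, deployment):
        base = [(1, "G00"), (24, "G00"), (30, "G11")]
        extended = base + [(40, "G22"), (50, "G00")]
        r1 = initial_stopover(make_track(deployment, base), grid_registry, CFG)
        r2 = initial_stopover(make_track(deployment, extended), grid_registry, CFG)
        assert r1.duration_days == r2.duration_days
        assert r1.end_index == r2.end_index

    def test_cluster_includes_nearby_receivers(self, deployment):
        # second receiver 2 km from anchor stays inside the cluster
        registry = {
            "A": Receiver("A", GeoPoint(54.0, 8.0)),
            "B": Receiver("B", GeoPoint(54.018, 8.0)),
            "C": Receiver("C", GeoPoint(54.3, 8.0)),
        }
        track = Track(
            deployment.tag_id,
            deployment,
            (
                Detection(deployment.tag_id, dt(1), "A"),
                Detection(deployment.tag_id, dt(20), "B"),
                Detection(deployment.tag_id, dt(48), "C"),
            ),
        )
        res = initial_stopover(track, registry, CFG)
        assert res.duration_days == pytest.approx(2.0)
        assert res.cluster_receiver_ids == {"A", "B"}


class TestClassifyExamples:
    def run_segments(self, track, registry):
        trs = transitions(track, registry, CFG.flight_speed_max_mps)
        return classify_segments(track, trs, CFG)

    def test_ninety_minute_dwell_is_stopover(self, grid_registry, deployment):
        track = make_track(deployment, [(0, "G11"), (0.75, "G11"), (1.5, "G11")])
        segs = self.run_segments(track, grid_registry)
        assert [s.label for s in segs] == [SegmentLabel.ALONG_TRACK_STOPOVER]

    def test_reasonable_speed_is_flight(self, grid_registry, deployment):
        # G00 -> G03 ~ 33.5 km in 1 h -> ~9.3 m/s
        track = make_track(deployment, [(0, "G00"), (1, "G03")])
        segs = self.run_segments(track, grid_registry)
        assert all(s.label is SegmentLabel.FLIGHT for s in segs)

    def test_slow_long_jump_is_unknown(self, deployment):
        # 40 km apart, crossed slowly: distance rule (< 32 km) violated
        registry = {
            "A": Receiver("A", GeoPoint(54.0, 8.0)),
            "B": Receiver("B", GeoPoint(54.36, 8.0)),  # ~40 km north
        }
        hours = 40_000 / 2.0 / 3600  # 2 m/s
        track = Track(
            deployment.tag_id,
            deployment,
            (
                Detection(deployment.tag_id, dt(0), "A"),
                Detection(deployment.tag_id, dt(hours), "B"),
            ),
        )
        trs = transitions(track, registry, CFG.flight_speed_max_mps)
        segs = classify_segments(track, trs, CFG)
        assert segs[1].label is SegmentLabel.UNKNOWN

    def test_slow_short_jump_within_window_is_stopover(self, grid_registry, deployment):
        # ~11 km in 2 h -> 1.5 m/s, gap < 3 d, distance < 32 km
        track = make_track(deployment, [(0, "G00"), (2, "G01")])
        segs = self.run_segments(track, grid_registry)
        assert segs[1].label is SegmentLabel.ALONG_TRACK_STOPOVER

    def test_short_visit_between_flights_is_flight(self, grid_registry, deployment):
        # 20-minute single-receiver visit flanked by flight transitions
        track = make_track(
            deployment, [(0, "G00"), (1, "G03"), (1 + 20 / 60, "G03"), (2.5, "G00")]
        )
        segs = self.run_segments(track, grid_registry)
        assert [s.label for s in segs] == [SegmentLabel.FLIGHT]

    def test_intermediate_dwell_is_unknown(self, grid_registry, deployment):
        # 45-minute dwell: above the 35-min flight rule, below the 1-h stop rule
        track = make_track(deployment, [(0, "G11"), (0.75, "G11")])
        segs = self.run_segments(track, grid_registry)
        assert [s.label for s in segs] == [SegmentLabel.UNKNOWN]

    def test_simultaneous_is_flight(self, grid_registry, deployment):
        track = make_track(deployment, [(0, "G00"), (0, "G01")])
        segs = self.run_segments(track, grid_registry)
        assert all(s.label is SegmentLabel.FLIGHT for s in segs)

    def test_segments_partition_timeline(self, grid_registry, deployment):
        rng = random.Random(5)
        for _ in range(25):
            track = random_small_track(rng, grid_registry, deployment)
            trs = transitions(track, grid_registry, CFG.flight_speed_max_mps)
            segs = classify_segments(track, trs, CFG)
            # contiguous, ordered, covering first to last detection
            assert segs[0].t_start == track.detections[0].t
            assert segs[-1].t_end == track.detections[-1].t
            for a, b in zip(segs, segs[1:]):
                assert a.t_end == b.t_start
                assert a.label is not b.label  # merged


# --- independent brute-force oracle ------------------------------------------


def brute_force_labels(track, registry, cfg):
    """Exhaustive per-detection/per-gap rule evaluation, no shared machinery.

    Returns (per-detection labels, per-gap labels) as plain strings.
    """
    dets = track.detections
    n = len(dets)
    det_labels = [None] * n
    # per-detection: find this detection's maximal same-receiver run by scanning
    for k in range(n):
        i = k
        while i > 0 and dets[i - 1].receiver_id == dets[k].receiver_id:
            i -= 1
        j = k
        while j + 1 < n and dets[j + 1].receiver_id == dets[k].receiver_id:
            j += 1
        dwell_s = (dets[j].t - dets[i].t).total_seconds()
        if dwell_s > cfg.stop_dwell_min_h * 3600:
            det_labels[k] = "along_track_stopover"
        elif dwell_s < cfg.short_visit_max_min * 60:
            det_labels[k] = "flight"
        else:
            det_labels[k] = "unknown"
    gap_labels = []
    for a in range(n - 1):
        if dets[a].receiver_id == dets[a + 1].receiver_id:
            continue
        pa = registry[dets[a].receiver_id].location
        pb = registry[dets[a + 1].receiver_id].location
        dist_m = great_circle_distance(pa, pb) * 1000
        dt_s = (dets[a + 1].t - dets[a].t).total_seconds()
        if dt_s == 0 or dist_m / dt_s > cfg.flight_speed_max_mps:
            gap_labels.append("flight")  # simultaneous
        elif dist_m / dt_s >= cfg.flight_speed_min_mps:
            gap_labels.append("flight")
        elif (
            dt_s <= cfg.stop_gap_max_days * 86400
            and dist_m / 1000 < cfg.stop_dist_max_km
        ):
            gap_labels.append("along_track_stopover")
        else:
            gap_labels.append("unknown")
    return det_labels, gap_labels


class TestOracleEquivalence:
    def test_brute_force_agreement_on_random_tracks(self, grid_registry, deployment):
        rng = random.Random(123)
        for _ in range(100):
            track = random_small_track(rng, grid_registry, deployment)
            trs = transitions(track, grid_registry, CFG.flight_speed_max_mps)
            want_det, want_gap = brute_force_labels(track, grid_registry, CFG)
            got_det = [lab.value for lab in detection_labels(track, CFG)]
            assert got_det == want_det
            from coasttrack.segmentation import label_transition

            got_gap = [label_transition(t, CFG).value for t in trs]
            assert got_gap == want_gap


class TestSummaryMetrics:
    def test_stopover_days_additive(self, deployment):
        mk = lambda d0, d1: Segment(  # noqa: E731
            "x", SegmentLabel.ALONG_TRACK_STOPOVER, dt(d0 * 24), dt(d1 * 24), ("G00",)
        )
        segs = [mk(0, 0.1), mk(1, 2.0)]
        assert along_track_stopover_days(segs) == pytest.approx(1.1)

    def test_no_stopovers_absent(self):
        segs = [Segment("x", SegmentLabel.FLIGHT, dt(0), dt(1), ("G00",))]
        assert along_track_stopover_days(segs) is None

    def test_days_at_study_area_calendar_difference(self, grid_registry, deployment):
        # release 2018-04-01 12:00; last detection 2018-04-16 -> 15 days
        track = make_track(deployment, [(1, "G00"), (15 * 24 - 10, "G11")])
        assert days_at_study_area(track) == 15

    def test_days_same_date_zero(self, grid_registry, deployment):
        track = make_track(deployment, [(1, "G00")])
        assert days_at_study_area(track) == 0

    def test_days_next_date_is_one(self, grid_registry, deployment):
        track = make_track(deployment, [(13, "G00")])  # 01:00 next day
        assert days_at_study_area(track) == 1

    def test_daily_mean_speed_whole_day_ceiling(self, deployment):
        # two receivers exactly 50 km apart, two qualifying flight transitions
        registry = {
            "A": Receiver("A", GeoPoint(54.0, 8.0)),
            "B": Receiver("B", GeoPoint(54.0 + 50 / 111.194926, 8.0)),
        }
        mk = lambda h, r: Detection(deployment.tag_id, dt(h), r)  # noqa: E731
        # each crossing takes 1.5 h (~9.26 m/s); total distance 100 km
        track = Track(
            deployment.tag_id,
            deployment,
            (mk(0, "A"), mk(1.5, "B"), mk(3.0, "A")),
        )
        trs = transitions(track, registry, CFG.flight_speed_max_mps)
        segs = classify_segments(track, trs, CFG)
        # 100 km over 3 h -> ceil(0.125 d) = 1 day
        assert daily_mean_speed(track, segs, trs, CFG) == pytest.approx(100.0, rel=1e-3)

    def test_daily_mean_speed_absent_without_movement(self, grid_registry, deployment):
        track = make_track(deployment, [(0, "G00"), (2, "G00")])
        trs = transitions(track, grid_registry, CFG.flight_speed_max_mps)
        segs = classify_segments(track, trs, CFG)
        assert daily_mean_speed(track, segs, trs, CFG) is None


class TestFlightStartPhase:
    def test_matches_night_fraction_conventions(self, grid_registry, deployment):
        loc = grid_registry["G00"].location
        from datetime import date

        sd = sun_events(date(2018, 4, 2), grid_registry["G00"].location)
        seg = Segment("x", SegmentLabel.FLIGHT, sd.sunset_utc, sd.sunset_utc, ("G00",))
        assert flight_start_phase(seg, grid_registry) == pytest.approx(0.0, abs=1e-6)

    def test_non_flight_segment_rejected(self, grid_registry):
        seg = Segment("x", SegmentLabel.UNKNOWN, dt(0), dt(1), ("G00",))
        with pytest.raises(ValueError):
            flight_start_phase(seg, grid_registry)
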