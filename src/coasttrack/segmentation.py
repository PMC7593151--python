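"""Behavioral segmentation of tracks and per-individual summary metrics.

A track is decomposed, after excision of the initial-stopover window, into
an alternating sequence of single-receiver *dwell runs* and inter-receiver
*transitions*. Rules, in order of precedence:

dwell runs
    longer than ``stop_dwell_min``            -> along-track stopover
    shorter than ``short_visit_max``          -> flight (brief passing visit)
    in between (uncovered by either rule)     -> unknown

transitions
    ground speed within [flight_speed_min, flight_speed_max], or
    flagged simultaneous                      -> flight
    slower, within ``stop_gap_max`` days and under ``stop_dist_max`` km
                                              -> along-track stopover
    any other slow transition                 -> unknown

Adjacent pieces with equal labels merge into one Segment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from datetime import datetime
from typing import Mapping, Sequence

from .detections_io import Detection, Receiver
from .geo_solar import great_circle_distance, night_fraction
from .track_builder import Track, Transition, transitions as _make_transitions

__all__ = [
    "SegmentLabel",
    "SegmentationConfig",
    "Segment",
    "InitialStopover",
    "IndividualSummary",
    "initial_stopover",
    "label_dwell_run",
    "label_transition",
    "classify_segments",
    "detection_labels",
    "segment_track",
    "along_track_stopover_days",
    "days_at_study_area",
    "daily_mean_speed",
    "flight_start_phase",
    "summarize_individual",
]

SECONDS_PER_DAY = 86400.0


class SegmentLabel(str, enum.Enum):
    INITIAL_STOPOVER = "initial_stopover"
    ALONG_TRACK_STOPOVER = "along_track_stopover"
    FLIGHT = "flight"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SegmentationConfig:
    """All numeric thresholds of the behavioral classification, in one place."""

    initial_radius_km: float = 20.0
    cluster_radius_km: float = 2.6
    stop_dwell_min_h: float = 1.0
    slow_speed_max_mps: float = 5.0
    flight_speed_min_mps: float = 5.0
    flight_speed_max_mps: float = 26.0
    short_visit_max_min: float = 35.0
    stop_gap_max_days: float = 3.0
    stop_dist_max_km: float = 32.0

    def __post_init__(self) -> None:
        if self.flight_speed_min_mps != self.slow_speed_max_mps:
            raise ValueError("flight_speed_min must equal slow_speed_max")
        for name in (
            "initial_radius_km",
            "cluster_radius_km",
            "stop_dwell_min_h",
            "slow_speed_max_mps",
            "flight_speed_max_mps",
            "short_visit_max_min",
            "stop_gap_max_days",
            "stop_dist_max_km",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_radius_km >= self.initial_radius_km:
            raise ValueError("cluster_radius must be smaller than initial_radius")


@dataclass(frozen=True)
class Segment:
    tag_id: str
    label: SegmentLabel
    t_start: datetime
    t_end: datetime
    receiver_ids: tuple[str, ...]

    @property
    def duration_days(self) -> float:
        return (self.t_end - self.t_start).total_seconds() / SECONDS_PER_DAY


@dataclass(frozen=True)
class InitialStopover:
    """Duration of the stopover at the release-site receiver cluster."""

    duration_days: float
    minimum_estimate: bool
    #: index into the track's detections of the first post-initial detection
    #: (== len(track) when the bird was never detected outside the cluster)
    end_index: int
    cluster_receiver_ids: frozenset[str]


@dataclass(frozen=True)
class IndividualSummary:
    tag_id: str
    species: str
    season: str
    initial_stopover_days: float | None
    initial_stopover_minimum: bool
    along_track_stopover_days: float | None
    has_along_track_stop: bool
    days_at_study_area: int
    daily_mean_speed_km_per_day: float | None


def initial_stopover(
    track: Track,
    registry: Mapping[str, Receiver],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> InitialStopover | None:
    """Stopover duration at the receiver cluster around the release site.

    The first receiver detecting the bird must lie within
    ``initial_radius_km`` of the release site; that receiver plus all
    registry receivers within ``cluster_radius_km`` of it form the cluster.
    Duration runs from release to the first detection outside the cluster.
    When the bird is never detected outside, the time to the last detection
    is returned flagged as a minimum estimate. Returns None when no initial
    stopover was recorded (first detection already far from release).
    """
    if len(track) == 0:
        return None
    first = track.detections[0]
    anchor = registry[first.receiver_id]
    release = track.deployment.release_site
    if great_circle_distance(anchor.location, release) > cfg.initial_radius_km:
        return None
    cluster = frozenset(
        rid
        for rid, rec in registry.items()
        if great_circle_distance(rec.location, anchor.location) <= cfg.cluster_radius_km
    ) | {anchor.receiver_id}
    for i, d in enumerate(track.detections):
        if d.receiver_id not in cluster:
            dur = (d.t - track.deployment.release_t).total_seconds() / SECONDS_PER_DAY
            return InitialStopover(dur, False, i, cluster)
    dur = (track.detections[-1].t - track.deployment.release_t).total_seconds() / SECONDS_PER_DAY
    return InitialStopover(dur, True, len(track.detections), cluster)


def label_dwell_run(duration_s: float, cfg: SegmentationConfig) -> SegmentLabel:
    """Label a maximal single-receiver run of detections by its duration."""
    if duration_s > cfg.stop_dwell_min_h * 3600.0:
        return SegmentLabel.ALONG_TRACK_STOPOVER
    if duration_s < cfg.short_visit_max_min * 60.0:
        return SegmentLabel.FLIGHT
    return SegmentLabel.UNKNOWN


def label_transition(tr: Transition, cfg: SegmentationConfig) -> SegmentLabel:
    """Label an inter-receiver transition by speed, gap and distance."""
    if tr.simultaneous:
        return SegmentLabel.FLIGHT
    speed = tr.ground_speed_mps
    if cfg.flight_speed_min_mps <= speed <= cfg.flight_speed_max_mps:
        return SegmentLabel.FLIGHT
    # slow movement (< flight_speed_min)
    if (
        tr.duration_s <= cfg.stop_gap_max_days * SECONDS_PER_DAY
        and tr.distance_km < cfg.stop_dist_max_km
    ):
        return SegmentLabel.ALONG_TRACK_STOPOVER
    return SegmentLabel.UNKNOWN


def _dwell_runs(dets: Sequence[Detection]) -> list[tuple[int, int]]:
    """Maximal same-receiver runs as (start, end) index pairs, end inclusive."""
    runs = []
    i = 0
    while i < len(dets):
        j = i
        while j + 1 < len(dets) and dets[j + 1].receiver_id == dets[i].receiver_id:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def classify_segments(
    track: Track,
    trs: Sequence[Transition],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[Segment]:
    """Segment a (post-initial) track into labeled behavioral stretches.

    ``trs`` must be the transitions of this same track. Every detection
    falls in exactly one dwell run; runs and the transitions between them
    are labeled independently, then adjacent equal labels merge.
    """
    dets = track.detections
    if not dets:
        return []
    runs = _dwell_runs(dets)
    if len(trs) != len(runs) - 1:
        raise ValueError(
            f"transitions ({len(trs)}) do not match dwell runs ({len(runs)}) of the track"
        )

    pieces: list[Segment] = []
    for k, (i, j) in enumerate(runs):
        dur = (dets[j].t - dets[i].t).total_seconds()
        pieces.append(
            Segment(
                tag_id=track.tag_id,
                label=label_dwell_run(dur, cfg),
                t_start=dets[i].t,
                t_end=dets[j].t,
                receiver_ids=(dets[i].receiver_id,),
            )
        )
        if k < len(trs):
            tr = trs[k]
            pieces.append(
                Segment(
                    tag_id=track.tag_id,
                    label=label_transition(tr, cfg),
                    t_start=tr.t_start,
                    t_end=tr.t_end,
                    receiver_ids=(tr.from_receiver, tr.to_receiver),
                )
            )

    merged: list[Segment] = []
    for seg in pieces:
        if merged and merged[-1].label is seg.label:
            prev = merged[-1]
            rids = prev.receiver_ids + tuple(
                r for r in seg.receiver_ids if r not in prev.receiver_ids
            )
            merged[-1] = replace(prev, t_end=seg.t_end, receiver_ids=rids)
        else:
            merged.append(seg)
    return merged


def detection_labels(
    track: Track,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[SegmentLabel]:
    """Label of each detection of a (post-initial) track = its dwell run's label."""
    dets = track.detections
    labels: list[SegmentLabel] = [SegmentLabel.UNKNOWN] * len(dets)
    for i, j in _dwell_runs(dets):
        lab = label_dwell_run((dets[j].t - dets[i].t).total_seconds(), cfg)
        for k in range(i, j + 1):
            labels[k] = lab
    return labels


def segment_track(
    track: Track,
    registry: Mapping[str, Receiver],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> tuple[InitialStopover | None, list[Segment], list[Transition]]:
    """Excise the initial stopover, then classify the remaining detections.

    Returns (initial stopover or None, segments of the post-initial track,
    transitions of the post-initial track).
    """
    ini = initial_stopover(track, registry, cfg)
    start = ini.end_index if ini is not None else 0
    rest = replace(track, detections=track.detections[start:])
    trs = _make_transitions(rest, registry, cfg.flight_speed_max_mps)
    return ini, classify_segments(rest, trs, cfg), trs


def along_track_stopover_days(segments: Sequence[Segment]) -> float | None:
    """Total along-track stopover time in days; None when there is none."""
    stops = [s for s in segments if s.label is SegmentLabel.ALONG_TRACK_STOPOVER]
    if not stops:
        return None
    return sum(s.duration_days for s in stops)


def days_at_study_area(track: Track) -> int:
    """Whole days between the release date and the date of the last detection."""
    if len(track) == 0:
        raise ValueError("empty track")
    last = max(d.t for d in track.detections)
    return (last.date() - track.deployment.release_t.date()).days


def daily_mean_speed(
    track: Track,
    segments: Sequence[Segment],
    trs: Sequence[Transition],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> float | None:
    """Distance over movement transitions divided by their span in whole days.

    Movement transitions are those labeled flight or along-track stopover
    (i.e. everything except unknown gaps). The denominator is the summed
    elapsed time of those transitions, rounded up to whole days (minimum 1).
    Returns None when there is no movement transition.
    """
    moving = [t for t in trs if label_transition(t, cfg) is not SegmentLabel.UNKNOWN]
    if not moving:
        return None
    dist = sum(t.distance_km for t in moving)
    span_days = sum(t.duration_s for t in moving) / SECONDS_PER_DAY
    return dist / max(1, math.ceil(span_days))


def flight_start_phase(segment: Segment, registry: Mapping[str, Receiver]) -> float:
    """Night-fraction of the flight segment's first detection (0=sunset, 1=sunrise)."""
    if segment.label is not SegmentLabel.FLIGHT:
        raise ValueError("flight_start_phase applies to flight segments")
    loc = registry[segment.receiver_ids[0]].location
    return night_fraction(segment.t_start, loc)


def summarize_individual(
    track: Track,
    registry: Mapping[str, Receiver],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> IndividualSummary:
    """Per-individual stopover/duration/speed metrics (one summary-table row)."""
    ini, segments, trs = segment_track(track, registry, cfg)
    at_days = along_track_stopover_days(segments)
    return IndividualSummary(
        tag_id=track.tag_id,
        species=track.deployment.species.value,
        season=track.deployment.season.value,
        initial_stopover_days=None if ini is None else ini.duration_days,
        initial_stopover_minimum=bool(ini is not None and ini.minimum_estimate),
        along_track_stopover_days=at_days,
        has_along_track_stop=at_days is not None,
        days_at_study_area=days_at_study_area(track),
        daily_mean_speed_km_per_day=daily_mean_speed(track, segments, trs, cfg),
    )
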