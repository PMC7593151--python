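"""Assemble per-individual tracks and inter-receiver transition kinematics."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Mapping, Sequence

from .detections_io import Deployment, Detection, Receiver
from .geo_solar import great_circle_distance, initial_bearing

__all__ = [
    "SIMULTANEOUS_SPEED_MPS",
    "Track",
    "Transition",
    "build_tracks",
    "transitions",
]

#: Implied ground speed (m/s) above which a receiver-to-receiver transition is
#: treated as a simultaneous detection rather than a flown movement.
SIMULTANEOUS_SPEED_MPS = 26.0


@dataclass(frozen=True)
class Track:
    """Time-ordered detection sequence of one individual with its deployment."""

    tag_id: str
    deployment: Deployment
    detections: tuple[Detection, ...]

    def __len__(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class Transition:
    """Movement between two consecutive detections at different receivers."""

    from_receiver: str
    to_receiver: str
    t_start: datetime
    t_end: datetime
    distance_km: float
    ground_speed_mps: float | None  # None when simultaneous (dt == 0)
    bearing_deg: float
    simultaneous: bool

    @property
    def duration_s(self) -> float:
        return (self.t_end - self.t_start).total_seconds()


def build_tracks(
    ds: Sequence[Detection], deployments: Mapping[str, Deployment]
) -> list[Track]:
    """Group detections by tag into tracks, sorted by release time then tag.

    Equal-timestamp duplicates at the same receiver are collapsed to the
    first occurrence. Every detected tag must have a deployment.
    """
    by_tag: dict[str, list[Detection]] = {}
    for d in ds:
        by_tag.setdefault(d.tag_id, []).append(d)
    missing = sorted(set(by_tag) - set(deployments))
    if missing:
        raise ValueError(f"detections for tags without a deployment: {missing}")

    tracks = []
    for tag_id, dets in by_tag.items():
        dets.sort(key=lambda d: d.t)
        deduped: list[Detection] = []
        seen: set[tuple[datetime, str]] = set()
        for d in dets:
            key = (d.t, d.receiver_id)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(d)
        tracks.append(Track(tag_id, deployments[tag_id], tuple(deduped)))
    tracks.sort(key=lambda tr: (tr.deployment.release_t, tr.tag_id))
    return tracks


def transitions(
    track: Track,
    registry: Mapping[str, Receiver],
    simultaneous_speed_mps: float = SIMULTANEOUS_SPEED_MPS,
) -> list[Transition]:
    """One Transition per consecutive detection pair at *different* receivers.

    Runs of detections at the same receiver collapse: the transition starts
    at the last detection before the receiver change. A transition whose
    implied ground speed exceeds ``simultaneous_speed_mps`` (including
    zero-elapsed-time pairs at distinct receivers) is flagged simultaneous;
    its ground_speed is None when elapsed time is zero.
    """
    out: list[Transition] = []
    dets = track.detections
    for prev, cur in zip(dets, dets[1:]):
        if prev.receiver_id == cur.receiver_id:
            continue
        a = registry[prev.receiver_id].location
        b = registry[cur.receiver_id].location
        dist = great_circle_distance(a, b)
        bearing = 0.0 if a == b else initial_bearing(a, b)
        dt = (cur.t - prev.t).total_seconds()
        if dt > 0:
            speed = dist * 1000.0 / dt
        else:
            speed = None
        simultaneous = speed is None or speed > simultaneous_speed_mps
        out.append(
            Transition(
                from_receiver=prev.receiver_id,
                to_receiver=cur.receiver_id,
                t_start=prev.t,
                t_end=cur.t,
                distance_km=dist,
                ground_speed_mps=speed,
                bearing_deg=bearing,
                simultaneous=simultaneous,
            )
        )
    return out
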