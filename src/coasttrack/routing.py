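"""Progress/detour decomposition and offshore/alongshore flight classification.

Headings are binned into a seasonal *progress* sector (315 deg through
north to 90 deg in spring; 135-270 deg in autumn, both ends inclusive);
everything else, including reverse movement, is a *detour*. Sustained
flights are maximal detection runs with bounded gaps that span enough
receivers or distance, classified offshore either by touching an island
receiver or by a latitude/longitude corridor criterion on where the bird
crossed the ``lat_split`` parallel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime
from itertools import combinations
from typing import Mapping, Sequence

from .detections_io import Detection, Receiver, Season
from .geo_solar import great_circle_distance
from .track_builder import Track, Transition

__all__ = [
    "Heading",
    "RouteLabel",
    "RoutingConfig",
    "SustainedFlight",
    "RouteSummary",
    "classify_heading",
    "route_lengths",
    "extract_sustained_flights",
    "first_sustained_flight",
    "classify_offshore",
]


class Heading(str, enum.Enum):
    PROGRESS = "progress"
    DETOUR = "detour"


class RouteLabel(str, enum.Enum):
    OFFSHORE = "offshore"
    ALONGSHORE = "alongshore"


@dataclass(frozen=True)
class RoutingConfig:
    progress_sector_spring: tuple[float, float] = (315.0, 90.0)  # wraps through north
    progress_sector_autumn: tuple[float, float] = (135.0, 270.0)
    sustained_min_receivers: int = 4
    sustained_receiver_spacing_km: float = 2.6
    sustained_pair_distance_km: float = 35.0
    sustained_gap_max_h: float = 7.0
    lat_split: float = 54.0
    offshore_lat_min: float = 54.135
    offshore_lon_threshold: float = 8.08

    def sector(self, season: Season) -> tuple[float, float]:
        return (
            self.progress_sector_spring
            if season is Season.SPRING
            else self.progress_sector_autumn
        )


@dataclass(frozen=True)
class SustainedFlight:
    tag_id: str
    detections: tuple[Detection, ...]
    receiver_ids: tuple[str, ...]  # distinct, in order of first appearance
    start_t: datetime
    label: RouteLabel | None = None


@dataclass(frozen=True)
class RouteSummary:
    tag_id: str
    progress_km: float
    detour_km: float

    @property
    def took_detour(self) -> bool:
        return self.detour_km > 0.0


def classify_heading(
    bearing: float, season: Season, cfg: RoutingConfig = RoutingConfig()
) -> Heading:
    """Progress if the bearing falls in the season's sector (ends inclusive)."""
    if not (0.0 <= bearing < 360.0):
        raise ValueError(f"bearing {bearing!r} outside [0, 360)")
    lo, hi = cfg.sector(season)
    if lo <= hi:
        inside = lo <= bearing <= hi
    else:  # sector wraps through north
        inside = bearing >= lo or bearing <= hi
    return Heading.PROGRESS if inside else Heading.DETOUR


def route_lengths(
    trs: Sequence[Transition],
    season: Season,
    cfg: RoutingConfig = RoutingConfig(),
    tag_id: str = "",
) -> RouteSummary:
    """Cumulative progress and detour track lengths over non-simultaneous transitions."""
    progress = detour = 0.0
    for tr in trs:
        if tr.simultaneous:
            continue
        if classify_heading(tr.bearing_deg, season, cfg) is Heading.PROGRESS:
            progress += tr.distance_km
        else:
            detour += tr.distance_km
    return RouteSummary(tag_id=tag_id, progress_km=progress, detour_km=detour)


def _has_spread_subset(
    locs: Sequence[tuple[str, float, float]],
    registry: Mapping[str, Receiver],
    k: int,
    min_spacing_km: float,
) -> bool:
    """True if some k receivers are pairwise more than min_spacing_km apart."""
    ids = [rid for rid, _, _ in locs]
    if len(ids) < k:
        return False
    far = {
        (a, b): great_circle_distance(registry[a].location, registry[b].location)
        > min_spacing_km
        for a, b in combinations(ids, 2)
    }
    for subset in combinations(ids, k):
        if all(far[(a, b)] for a, b in combinations(subset, 2)):
            return True
    return False


def extract_sustained_flights(
    track: Track,
    registry: Mapping[str, Receiver],
    cfg: RoutingConfig = RoutingConfig(),
) -> list[SustainedFlight]:
    """Qualifying continuous multi-receiver flight windows, in time order.

    Candidate windows are maximal detection runs whose consecutive time
    gaps are all below ``sustained_gap_max_h``. A window qualifies when it
    involves at least ``sustained_min_receivers`` distinct receivers that
    are pairwise more than ``sustained_receiver_spacing_km`` apart, or two
    receivers at least ``sustained_pair_distance_km`` apart.
    """
    dets = track.detections
    if not dets:
        return []
    max_gap_s = cfg.sustained_gap_max_h * 3600.0
    windows: list[list[Detection]] = [[dets[0]]]
    for prev, cur in zip(dets, dets[1:]):
        if (cur.t - prev.t).total_seconds() < max_gap_s:
            windows[-1].append(cur)
        else:
            windows.append([cur])

    out: list[SustainedFlight] = []
    for win in windows:
        rids: list[str] = []
        for d in win:
            if d.receiver_id not in rids:
                rids.append(d.receiver_id)
        if len(rids) < 2:
            continue
        locs = [(r, registry[r].location.lat, registry[r].location.lon) for r in rids]
        max_pair = max(
            great_circle_distance(registry[a].location, registry[b].location)
            for a, b in combinations(rids, 2)
        )
        qualifies = max_pair >= cfg.sustained_pair_distance_km or _has_spread_subset(
            locs, registry, cfg.sustained_min_receivers, cfg.sustained_receiver_spacing_km
        )
        if qualifies:
            out.append(
                SustainedFlight(
                    tag_id=track.tag_id,
                    detections=tuple(win),
                    receiver_ids=tuple(rids),
                    start_t=win[0].t,
                )
            )
    return out


def first_sustained_flight(
    flights: Sequence[SustainedFlight],
) -> SustainedFlight | None:
    """Earliest sustained flight by start time; None when there is none."""
    if not flights:
        return None
    return min(flights, key=lambda f: f.start_t)


def classify_offshore(
    f: SustainedFlight,
    season: Season,
    registry: Mapping[str, Receiver],
    cfg: RoutingConfig = RoutingConfig(),
) -> RouteLabel:
    """Offshore vs alongshore label of a sustained flight.

    Offshore if any involved receiver is an island site, or if the flight
    crossed the ``lat_split`` parallel through the open-bay corridor: in
    autumn (southbound) the *last* detection north of the split must be at
    latitude above ``offshore_lat_min`` and the *first* detection south of
    it at longitude below ``offshore_lon_threshold``; in spring
    (northbound) the temporal roles mirror (first north / last south).
    Alongshore otherwise, including flights that never cross the parallel.
    """
    if any(registry[r].is_island_site for r in f.receiver_ids):
        return RouteLabel.OFFSHORE

    above = [d for d in f.detections if registry[d.receiver_id].location.lat > cfg.lat_split]
    below = [d for d in f.detections if registry[d.receiver_id].location.lat < cfg.lat_split]
    if not above or not below:
        return RouteLabel.ALONGSHORE

    if season is Season.AUTUMN:
        north_side = above[-1]  # last detection before crossing southward
        south_side = below[0]  # first detection after crossing
    else:
        north_side = above[0]  # first detection after crossing northward
        south_side = below[-1]  # last detection before crossing
    lat_ok = registry[north_side.receiver_id].location.lat > cfg.offshore_lat_min
    lon_ok = registry[south_side.receiver_id].location.lon < cfg.offshore_lon_threshold
    return RouteLabel.OFFSHORE if lat_ok and lon_ok else RouteLabel.ALONGSHORE
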