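"""Synthetic detection-data generator with ground truth.

Simulates individually tagged birds of two archetypes — a diurnal migrant
that flies around sunrise and a nocturnal migrant that departs in the
first quarter of the night — moving along a two-leg coastal receiver
array enclosing a bay, with an offshore island site. Movement is latent
waypoint-to-waypoint flight at a sampled ground speed, alternating with
stationary stopover bouts; the emitted table contains only receiver-bound
detections (plus optional injected false positives), exactly the input
shape expected by :mod:`coasttrack.detections_io`.

Every random draw flows from ``SimConfig.seed``, so identical configs
produce byte-identical detection tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np

from .detections_io import Deployment, Detection, Receiver, Season, Species
from .geo_solar import (
    EARTH_RADIUS_KM,
    GeoPoint,
    great_circle_distance,
    initial_bearing,
    sun_events,
)
from .routing import RouteLabel

__all__ = [
    "TruthLabel",
    "ArchetypeParams",
    "SimConfig",
    "LatentInterval",
    "LatentTrajectory",
    "TruthRecord",
    "SimDataset",
    "make_receiver_array",
    "simulate_tracks",
    "emit_detections",
    "simulate_dataset",
]


class TruthLabel(str, enum.Enum):
    INITIAL_STOPOVER = "initial_stopover"
    FLIGHT = "flight"
    STOPOVER = "stopover"


@dataclass(frozen=True)
class ArchetypeParams:
    """Behavioral parameters of one species archetype."""

    nocturnal: bool
    #: ground speed draw (m/s), clipped to [speed_lo, speed_hi]
    speed_mean_mps: float = 12.0
    speed_sd_mps: float = 1.0
    speed_lo_mps: float = 10.5
    speed_hi_mps: float = 15.0
    #: uniform bounds (days) of the intended initial-stopover duration
    initial_stop_days: tuple[float, float] = (1.5, 8.0)
    #: probability of an along-track stopover at each intermediate waypoint
    p_stop: float = 0.3
    stop_days: tuple[float, float] = (0.3, 2.5)
    p_offshore: float = 0.3
    #: nocturnal departure phase: uniform night-fraction window after sunset
    night_phase: tuple[float, float] = (0.05, 0.25)
    #: diurnal departure offset relative to sunrise (hours): normal draw
    #: centered at sunrise, clipped so starts extend ~3 h before sunrise
    sunrise_offset_mean_h: float = 0.0
    sunrise_offset_sd_h: float = 1.25
    sunrise_offset_h: tuple[float, float] = (-3.0, 2.0)
    #: diurnal flight window closes this many hours after sunrise
    day_window_end_h: float = 5.0


def _default_archetypes() -> dict[Species, ArchetypeParams]:
    return {
        Species.DUNNOCK: ArchetypeParams(
            nocturnal=False,
            initial_stop_days=(2.0, 10.0),
            p_stop=0.25,
            p_offshore=0.35,
        ),
        Species.BLACKCAP: ArchetypeParams(
            nocturnal=True,
            initial_stop_days=(0.3, 1.5),
            p_stop=0.06,
            p_offshore=0.3,
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    n_birds_per_species_season: int = 8
    seasons: tuple[Season, ...] = (Season.SPRING, Season.AUTUMN)
    species: tuple[Species, ...] = (Species.DUNNOCK, Species.BLACKCAP)
    p_detect: float = 1.0
    detection_range_km: float = 10.0
    fp_rate: float = 0.0
    p_detour: float = 0.15
    dt_move_s: float = 120.0
    dt_stationary_s: float = 300.0
    year: int = 2018
    archetypes: Mapping[Species, ArchetypeParams] = field(default_factory=_default_archetypes)

    def __post_init__(self) -> None:
        for p in (self.p_detect, self.fp_rate, self.p_detour):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_birds_per_species_season < 1:
            raise ValueError("need at least one bird per species and season")


# --- receiver geography -------------------------------------------------------

# East (north-south) coastline leg, north to south, at lon 8.60.
_EAST_LEG = [(f"E{i + 1}", lat, 8.60) for i, lat in enumerate(
    (55.05, 54.85, 54.65, 54.45, 54.25, 54.05)
)]
# South (east-west) coastline leg, east to west, at lat 53.60.
_SOUTH_LEG = [(f"S{i + 1}", 53.60, lon) for i, lon in enumerate(
    (8.45, 8.20, 7.95, 7.70, 7.45, 7.20, 6.95)
)]
_ISLAND = ("HEL", 54.1821, 7.8925)

#: release sites coincide with one coastal receiver per season
_RELEASE = {Season.SPRING: "S2", Season.AUTUMN: "E4"}


def make_receiver_array(cfg: SimConfig | None = None) -> dict[str, Receiver]:
    """Default two-leg coastal registry with one flagged island site."""
    registry: dict[str, Receiver] = {}
    for rid, lat, lon in _EAST_LEG + _SOUTH_LEG:
        registry[rid] = Receiver(rid, GeoPoint(lat, lon), is_island_site=False)
    rid, lat, lon = _ISLAND
    registry[rid] = Receiver(rid, GeoPoint(lat, lon), is_island_site=True)
    return registry


def _routes(season: Season) -> dict[RouteLabel, list[str]]:
    if season is Season.AUTUMN:
        return {
            RouteLabel.ALONGSHORE: ["E4", "E5", "E6", "S1", "S2", "S3", "S4", "S5", "S6", "S7"],
            RouteLabel.OFFSHORE: ["E4", "HEL", "S3", "S4", "S5", "S6", "S7"],
        }
    return {
        RouteLabel.ALONGSHORE: ["S2", "S1", "E6", "E5", "E4", "E3", "E2", "E1"],
        RouteLabel.OFFSHORE: ["S2", "S4", "HEL", "E4", "E3", "E2", "E1"],
    }


# --- latent model -------------------------------------------------------------

@dataclass(frozen=True)
class LatentInterval:
    t0: datetime
    t1: datetime
    label: TruthLabel
    start: GeoPoint
    end: GeoPoint


@dataclass(frozen=True)
class LatentTrajectory:
    tag_id: str
    deployment: Deployment
    intervals: tuple[LatentInterval, ...]
    route_label: RouteLabel


@dataclass
class TruthRecord:
    tag_id: str
    route_label: RouteLabel
    initial_stopover_days: float
    intervals: tuple[tuple[datetime, datetime, TruthLabel], ...]
    detour_leg_count: int
    has_along_track_stop: bool
    false_positive_keys: frozenset[tuple[str, str]] = frozenset()

    def label_at(self, t: datetime) -> TruthLabel | None:
        for t0, t1, lab in self.intervals:
            if t0 <= t <= t1:
                return lab
        return None


def _round_s(t: datetime) -> datetime:
    return t.replace(microsecond=0)


def _release_window(species: Species, season: Season, year: int) -> date:
    if season is Season.SPRING:
        return date(year, 3, 20) if species is Species.DUNNOCK else date(year, 4, 8)
    return date(year, 10, 3)


def _next_flight_window(
    earliest: datetime,
    loc: GeoPoint,
    arch: ArchetypeParams,
    rng: np.random.Generator,
) -> tuple[datetime, datetime]:
    """First (start, end) flight window whose start is at or after ``earliest``."""
    d = earliest.date() - timedelta(days=1)
    for _ in range(1000):
        if arch.nocturnal:
            sunset = sun_events(d, loc).sunset_utc
            sunrise = sun_events(d + timedelta(days=1), loc).sunrise_utc
            u = rng.uniform(*arch.night_phase)
            start = sunset + timedelta(seconds=u * (sunrise - sunset).total_seconds())
            end = sunrise - timedelta(minutes=10)
        else:
            sunrise = sun_events(d, loc).sunrise_utc
            off = float(
                np.clip(
                    rng.normal(arch.sunrise_offset_mean_h, arch.sunrise_offset_sd_h),
                    *arch.sunrise_offset_h,
                )
            )
            start = sunrise + timedelta(hours=off)
            end = sunrise + timedelta(hours=arch.day_window_end_h)
        if start >= earliest:
            return _round_s(start), _round_s(end)
        d += timedelta(days=1)
    raise RuntimeError("no flight window found")  # pragma: no cover


def _simulate_bird(
    tag_id: str,
    species: Species,
    season: Season,
    registry: Mapping[str, Receiver],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[LatentTrajectory, TruthRecord]:
    arch = cfg.archetypes[species]
    release_rid = _RELEASE[season]
    release_site = registry[release_rid].location

    day0 = _release_window(species, season, cfg.year)
    release_t = _round_s(
        datetime(day0.year, day0.month, day0.day, 9, tzinfo=timezone.utc)
        + timedelta(days=int(rng.integers(0, 8)), seconds=float(rng.uniform(0, 6 * 3600)))
    )
    fat_mu, fat_sd = (3.0, 0.7) if species is Species.DUNNOCK else (3.75, 0.9)
    fat = float(np.clip(np.round(rng.normal(fat_mu, fat_sd) * 4) / 4, 0.0, 8.0))
    deployment = Deployment(tag_id, species, season, release_t, release_site, fat)

    speed = float(np.clip(rng.normal(arch.speed_mean_mps, arch.speed_sd_mps),
                          arch.speed_lo_mps, arch.speed_hi_mps))
    route_label = (
        RouteLabel.OFFSHORE if rng.random() < arch.p_offshore else RouteLabel.ALONGSHORE
    )
    waypoints = [registry[r].location for r in _routes(season)[route_label]]

    # optional single backtrack leg (a "detour") at one intermediate waypoint
    detour_at = None
    if cfg.p_detour > 0 and rng.random() < cfg.p_detour and len(waypoints) > 3:
        detour_at = int(rng.integers(2, len(waypoints) - 1))

    # stopover plan per intermediate waypoint
    stops = {
        i: float(rng.uniform(*arch.stop_days))
        for i in range(1, len(waypoints) - 1)
        if rng.random() < arch.p_stop
    }

    # --- initial stopover
    intended = float(rng.uniform(*arch.initial_stop_days))
    dep_start, dep_end = _next_flight_window(
        release_t + timedelta(days=intended), release_site, arch, rng
    )
    intervals: list[LatentInterval] = [
        LatentInterval(release_t, dep_start, TruthLabel.INITIAL_STOPOVER, release_site, release_site)
    ]
    initial_days = (dep_start - release_t).total_seconds() / 86400.0

    # --- fly the route
    # visited waypoint-index sequence, with an optional backtrack inserted
    seq = list(range(len(waypoints)))
    if detour_at is not None:
        seq = seq[: detour_at + 1] + [detour_at - 1] + seq[detour_at:]
    legs = [(waypoints[a], waypoints[b]) for a, b in zip(seq, seq[1:])]

    # a planned stopover applies on first arrival at its waypoint
    stop_after: dict[int, float] = {}
    arrived: set[int] = {seq[0]}
    for li, wi in enumerate(seq[1:]):
        if wi in stops and wi not in arrived:
            stop_after[li] = stops[wi]
        arrived.add(wi)

    t, w_end = dep_start, dep_end
    detour_count = 0
    for li, (a, b) in enumerate(legs):
        dist_km = great_circle_distance(a, b)
        flight_s = dist_km * 1000.0 / speed
        if (w_end - t).total_seconds() < flight_s:
            # leg does not fit in the remaining window: wait here until the next one
            nxt, nxt_end = _next_flight_window(w_end, a, arch, rng)
            intervals.append(LatentInterval(t, nxt, TruthLabel.STOPOVER, a, a))
            t, w_end = nxt, nxt_end
        t1 = _round_s(t + timedelta(seconds=flight_s))
        intervals.append(LatentInterval(t, t1, TruthLabel.FLIGHT, a, b))
        brg = initial_bearing(a, b) if a != b else 0.0
        lo, hi = (315.0, 90.0) if season is Season.SPRING else (135.0, 270.0)
        inside = (brg >= lo or brg <= hi) if lo > hi else (lo <= brg <= hi)
        if not inside:
            detour_count += 1
        t = t1
        if li in stop_after:
            resume, resume_end = _next_flight_window(
                t + timedelta(days=stop_after[li]), b, arch, rng
            )
            intervals.append(LatentInterval(t, resume, TruthLabel.STOPOVER, b, b))
            t, w_end = resume, resume_end

    truth_intervals = tuple((iv.t0, iv.t1, iv.label) for iv in intervals)
    has_stop = any(iv.label is TruthLabel.STOPOVER for iv in intervals)
    traj = LatentTrajectory(tag_id, deployment, tuple(intervals), route_label)
    truth = TruthRecord(
        tag_id=tag_id,
        route_label=route_label,
        initial_stopover_days=initial_days,
        intervals=truth_intervals,
        detour_leg_count=detour_count,
        has_along_track_stop=has_stop,
    )
    return traj, truth


def simulate_tracks(
    cfg: SimConfig, registry: Mapping[str, Receiver] | None = None
) -> tuple[list[LatentTrajectory], list[TruthRecord]]:
    """Simulate latent trajectories plus ground truth for all configured birds."""
    if registry is None:
        registry = make_receiver_array(cfg)
    rng = np.random.default_rng(cfg.seed)
    trajectories, truths = [], []
    n = 0
    for season in cfg.seasons:
        for species in cfg.species:
            for _ in range(cfg.n_birds_per_species_season):
                n += 1
                tag = f"tag{n:03d}"
                traj, truth = _simulate_bird(tag, species, season, registry, cfg, rng)
                trajectories.append(traj)
                truths.append(truth)
    return trajectories, truths


# --- detection emission -------------------------------------------------------

def _haversine_km(lat1, lon1, lat2, lon2):
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def emit_detections(
    trajectories: Sequence[LatentTrajectory],
    registry: Mapping[str, Receiver],
    cfg: SimConfig,
) -> tuple[list[Detection], dict[str, frozenset[tuple[str, str]]]]:
    """Thin latent trajectories into a detection table.

    A detection fires whenever the bird is within ``detection_range_km`` of
    a receiver at a sample instant, with probability ``p_detect``; false
    positives are injected at rate ``fp_rate`` per true detection with
    fp_score drawn at or above 0.67 so the standard filter removes them.

    Returns the detections (sorted by tag, time) and, per tag, the set of
    (iso-timestamp, receiver_id) keys of the injected false positives.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_654_321]))
    rids = list(registry)
    rlat = np.array([registry[r].location.lat for r in rids])
    rlon = np.array([registry[r].location.lon for r in rids])

    detections: list[Detection] = []
    fp_keys: dict[str, frozenset[tuple[str, str]]] = {}
    for traj in trajectories:
        rows: list[tuple[datetime, str]] = []
        for iv in traj.intervals:
            dur = (iv.t1 - iv.t0).total_seconds()
            if dur <= 0:
                continue
            dt = cfg.dt_move_s if iv.label is TruthLabel.FLIGHT else cfg.dt_stationary_s
            offsets = np.arange(0.0, dur + 1e-9, dt)
            frac = offsets / dur if dur > 0 else np.zeros_like(offsets)
            lats = iv.start.lat + frac * (iv.end.lat - iv.start.lat)
            lons = iv.start.lon + frac * (iv.end.lon - iv.start.lon)
            dists = _haversine_km(lats[:, None], lons[:, None], rlat[None, :], rlon[None, :])
            in_range = dists <= cfg.detection_range_km
            if cfg.p_detect < 1.0:
                in_range &= rng.random(in_range.shape) < cfg.p_detect
            for ti, ri in zip(*np.nonzero(in_range)):
                rows.append(
                    (
                        _round_s(iv.t0 + timedelta(seconds=float(offsets[ti]))),
                        rids[ri],
                    )
                )
        # genuine rows: low fp score, some missing
        scores = rng.uniform(0.0, 0.5, size=len(rows))
        missing = rng.random(len(rows)) < 0.1
        for (t, rid), sc, miss in zip(rows, scores, missing):
            detections.append(
                Detection(traj.tag_id, t, rid, None if miss else round(float(sc), 4))
            )
        # injected false positives: score at or above the standard threshold
        keys: set[tuple[str, str]] = set()
        if cfg.fp_rate > 0 and rows:
            n_fp = int(rng.poisson(cfg.fp_rate * len(rows)))
            t0 = traj.deployment.release_t
            span = (traj.intervals[-1].t1 - t0).total_seconds()
            for _ in range(n_fp):
                t = _round_s(t0 + timedelta(seconds=float(rng.uniform(0, span))))
                rid = rids[int(rng.integers(0, len(rids)))]
                sc = round(float(rng.uniform(0.67, 0.995)), 4)
                detections.append(Detection(traj.tag_id, t, rid, sc))
                keys.add((t.isoformat(), rid))
        fp_keys[traj.tag_id] = frozenset(keys)
    detections.sort(key=lambda d: (d.tag_id, d.t, d.receiver_id))
    return detections, fp_keys


@dataclass(frozen=True)
class SimDataset:
    registry: dict[str, Receiver]
    deployments: dict[str, Deployment]
    detections: list[Detection]
    truths: list[TruthRecord]


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """End-to-end convenience: registry + deployments + detections + truth."""
    registry = make_receiver_array(cfg)
    trajectories, truths = simulate_tracks(cfg, registry)
    detections, fp_keys = emit_detections(trajectories, registry, cfg)
    for tr in truths:
        tr.false_positive_keys = fp_keys.get(tr.tag_id, frozenset())
    deployments = {t.tag_id: t.deployment for t in trajectories}
    return SimDataset(registry, deployments, detections, truths)
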