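"""Read and validate detection, receiver and deployment tables.

All three tables are plain CSV. The canonical dialect is comma-separated
UTF-8 with ISO-8601 UTC timestamps; epoch seconds are also accepted on
read. Detections carry an optional per-row probability of being a false
positive (produced upstream by an external classifier); rows at or above
a configurable threshold are dropped by :func:`filter_false_positives`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .geo_solar import GeoPoint

__all__ = [
    "Source",
    "Species",
    "Season",
    "Receiver",
    "Detection",
    "Deployment",
    "FilterConfig",
    "ValidationError",
    "read_receivers",
    "read_deployments",
    "read_detections",
    "write_detections",
    "write_receivers",
    "write_deployments",
    "filter_false_positives",
]


class Source(str, Enum):
    NETWORK = "network"
    RECAPTURE = "recapture"


class Species(str, Enum):
    DUNNOCK = "dunnock"
    BLACKCAP = "blackcap"


class Season(str, Enum):
    SPRING = "spring"
    AUTUMN = "autumn"


class ValidationError(ValueError):
    """Input table violates its contract (unknown ids, bad rows)."""


@dataclass(frozen=True)
class Receiver:
    receiver_id: str
    location: GeoPoint
    is_island_site: bool = False


@dataclass(frozen=True)
class Detection:
    tag_id: str
    t: datetime
    receiver_id: str
    fp_score: float | None = None
    source: Source = Source.NETWORK

    def __post_init__(self) -> None:
        if self.fp_score is not None and not (0.0 <= self.fp_score <= 1.0):
            raise ValueError(f"fp_score {self.fp_score!r} outside [0, 1]")


@dataclass(frozen=True)
class Deployment:
    tag_id: str
    species: Species
    season: Season
    release_t: datetime
    release_site: GeoPoint
    fat_score: float | None = None


@dataclass(frozen=True)
class FilterConfig:
    """Threshold on the false-positive probability score (drop if >= threshold)."""

    fp_threshold: float = 0.67

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_threshold <= 1.0):
            raise ValueError("fp_threshold must lie in [0, 1]")


def _parse_ts(value: object, where: str) -> datetime:
    """Parse ISO-8601 or epoch-seconds timestamps to tz-aware UTC."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return datetime.fromtimestamp(float(value), tz=timezone.utc)
    s = str(value).strip()
    try:
        return datetime.fromtimestamp(float(s), tz=timezone.utc)
    except ValueError:
        pass
    try:
        t = datetime.fromisoformat(s.replace("Z", "+00:00"))
    except ValueError as exc:
        raise ValidationError(f"unparseable timestamp {value!r} at {where}") from exc
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def read_receivers(path: str | Path) -> dict[str, Receiver]:
    """Read a receiver registry CSV (receiver_id, lat, lon, is_island_site)."""
    df = pd.read_csv(path, dtype={"receiver_id": str})
    required = {"receiver_id", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"receiver registry missing columns: {sorted(missing)}")
    registry: dict[str, Receiver] = {}
    for row in df.itertuples(index=False):
        rid = str(row.receiver_id)
        if rid in registry:
            raise ValidationError(f"duplicate receiver_id {rid!r} in registry")
        island = bool(getattr(row, "is_island_site", False))
        registry[rid] = Receiver(rid, GeoPoint(float(row.lat), float(row.lon)), island)
    return registry


def read_deployments(path: str | Path) -> dict[str, Deployment]:
    """Read the deployment table CSV (tag_id, species, season, release_ts_utc, lat, lon, fat_score)."""
    df = pd.read_csv(path, dtype={"tag_id": str})
    required = {"tag_id", "species", "season", "release_ts_utc", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"deployment table missing columns: {sorted(missing)}")
    out: dict[str, Deployment] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tid = str(row.tag_id)
        if tid in out:
            raise ValidationError(f"duplicate deployment for tag {tid!r}")
        fat = getattr(row, "fat_score", None)
        fat = None if fat is None or pd.isna(fat) else float(fat)
        out[tid] = Deployment(
            tag_id=tid,
            species=Species(str(row.species)),
            season=Season(str(row.season)),
            release_t=_parse_ts(row.release_ts_utc, f"line {i}"),
            release_site=GeoPoint(float(row.lat), float(row.lon)),
            fat_score=fat,
        )
    return out


def read_detections(
    path: str | Path, registry: Mapping[str, Receiver]
) -> list[Detection]:
    """Read a detection CSV and resolve receiver ids against the registry.

    Required columns: ``tag_id``, ``ts_utc`` (ISO-8601 or epoch seconds),
    ``receiver_id``. Optional: ``fp_score``, ``source``. Output is sorted
    by (tag_id, time) regardless of row order on disk.

    Raises
    ------
    ValidationError
        On missing columns, receiver ids absent from the registry
        (all offenders listed) or unparseable timestamps (with line number).
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "receiver_id": str})
    required = {"tag_id", "ts_utc", "receiver_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"detection table missing columns: {sorted(missing)}")

    unknown = sorted(set(df["receiver_id"].astype(str)) - set(registry))
    if unknown:
        raise ValidationError(f"unknown receiver ids: {unknown}")

    has_fp = "fp_score" in df.columns
    has_src = "source" in df.columns
    dets: list[Detection] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        fp = None
        if has_fp and not pd.isna(row.fp_score):
            fp = float(row.fp_score)
        src = Source(str(row.source)) if has_src else Source.NETWORK
        dets.append(
            Detection(
                tag_id=str(row.tag_id),
                t=_parse_ts(row.ts_utc, f"line {i}"),
                receiver_id=str(row.receiver_id),
                fp_score=fp,
                source=src,
            )
        )
    dets.sort(key=lambda d: (d.tag_id, d.t))
    return dets


def write_detections(dets: Iterable[Detection], path: str | Path) -> None:
    """Write detections in the canonical CSV dialect (ISO-8601 UTC timestamps)."""
    rows = [
        {
            "tag_id": d.tag_id,
            "ts_utc": d.t.astimezone(timezone.utc).isoformat().replace("+00:00", "Z"),
            "receiver_id": d.receiver_id,
            "fp_score": "" if d.fp_score is None else d.fp_score,
            "source": d.source.value,
        }
        for d in dets
    ]
    pd.DataFrame(rows, columns=["tag_id", "ts_utc", "receiver_id", "fp_score", "source"]).to_csv(
        path, index=False
    )


def write_receivers(registry: Mapping[str, Receiver], path: str | Path) -> None:
    """Write a receiver registry in the canonical CSV dialect."""
    rows = [
        {
            "receiver_id": r.receiver_id,
            "lat": r.location.lat,
            "lon": r.location.lon,
            "is_island_site": r.is_island_site,
        }
        for r in registry.values()
    ]
    pd.DataFrame(rows, columns=["receiver_id", "lat", "lon", "is_island_site"]).to_csv(
        path, index=False
    )


def write_deployments(deployments: Mapping[str, Deployment], path: str | Path) -> None:
    """Write a deployment table in the canonical CSV dialect."""
    rows = [
        {
            "tag_id": d.tag_id,
            "species": d.species.value,
            "season": d.season.value,
            "release_ts_utc": d.release_t.astimezone(timezone.utc)
            .isoformat()
            .replace("+00:00", "Z"),
            "lat": d.release_site.lat,
            "lon": d.release_site.lon,
            "fat_score": "" if d.fat_score is None else d.fat_score,
        }
        for d in deployments.values()
    ]
    pd.DataFrame(
        rows,
        columns=["tag_id", "species", "season", "release_ts_utc", "lat", "lon", "fat_score"],
    ).to_csv(path, index=False)


def filter_false_positives(
    ds: Sequence[Detection], cfg: FilterConfig = FilterConfig()
) -> list[Detection]:
    """Drop detections whose fp_score is at or above the threshold.

    Rows with a missing score and recapture-source rows are always kept.
    Idempotent; output preserves input order.
    """
    return [
        d
        for d in ds
        if d.source is Source.RECAPTURE
        or d.fp_score is None
        or d.fp_score < cfg.fp_threshold
    ]
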