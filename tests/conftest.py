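from __future__ import annotations

import random
from datetime import datetime, timedelta, timezone

import pytest

from coasttrack.detections_io import (
    Deployment,
    Detection,
    Receiver,
    Season,
    Species,
)
from coasttrack.geo_solar import GeoPoint
from coasttrack.synthetic_data import SimConfig, simulate_dataset
from coasttrack.track_builder import Track

T0 = datetime(2018, 4, 1, 12, 0, tzinfo=timezone.utc)


def dt(hours: float) -> datetime:
    return T0 + timedelta(hours=hours)


@pytest.fixture(scope="session")
def grid_registry() -> dict[str, Receiver]:
    """5x5 receiver grid, ~11 km spacing, for constructed-track tests."""
    registry = {}
    for i in range(5):
        for j in range(5):
            rid = f"G{i}{j}"
            registry[rid] = Receiver(rid, GeoPoint(54.0 + 0.1 * i, 8.0 + 0.17 * j))
    return registry


@pytest.fixture
def deployment() -> Deployment:
    return Deployment(
        tag_id="bird1",
        species=Species.DUNNOCK,
        season=Season.SPRING,
        release_t=T0,
        release_site=GeoPoint(54.0, 8.0),
        fat_score=3.0,
    )


def make_track(deployment: Deployment, points: list[tuple[float, str]]) -> Track:
    """Track from (hours-after-release, receiver_id) pairs."""
    dets = tuple(
        Detection(deployment.tag_id, dt(h), rid) for h, rid in points
    )
    return Track(deployment.tag_id, deployment, dets)


@pytest.fixture(scope="session")
def sim_dataset():
    """Shared small synthetic dataset (dense coverage, no false positives)."""
    return simulate_dataset(SimConfig(seed=7, n_birds_per_species_season=3))


def random_small_track(
    rng: random.Random,
    registry: dict[str, Receiver],
    deployment: Deployment,
    max_n: int = 50,
) -> Track:
    """Random track over the grid registry with mixed dwell/flight timing."""
    rids = list(registry)
    n = rng.randint(2, max_n)
    t = T0
    rid = rng.choice(rids)
    dets = []
    for _ in range(n):
        dets.append(Detection(deployment.tag_id, t, rid))
        move = rng.random()
        if move < 0.45:  # stay, dwell a random amount
            t += timedelta(minutes=rng.choice([2, 10, 40, 80, 200]))
        else:  # hop to another receiver with a random elapsed time
            rid = rng.choice([r for r in rids if r != rid])
            t += timedelta(minutes=rng.choice([0, 1, 20, 60, 180, 600, 3000, 6000]))
    return Track(deployment.tag_id, deployment, tuple(dets))
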