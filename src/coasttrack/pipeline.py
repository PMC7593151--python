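"""End-to-end orchestration: filter -> tracks -> segmentation -> routing -> stats.

``run_pipeline`` produces four artifacts in the output directory:

individual_summary.csv
    one row per detected individual (stopover/duration/speed metrics plus
    progress/detour lengths and the offshore/alongshore label of the first
    sustained flight)
group_summary.csv
    median (25%, 75%) per species x season for each summary variable, with
    the between-species Kruskal-Wallis statistic per season
proportion_tests.csv
    count contingencies and continuity-corrected equal-proportions
    chi-square comparisons (initial stopover, along-track stopover,
    detours, offshore flights)
manifest.json
    configuration echo, stage record counts and library versions
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detections_io import (
    FilterConfig,
    Season,
    filter_false_positives,
    read_deployments,
    read_detections,
    read_receivers,
)
from .routing import (
    RoutingConfig,
    classify_offshore,
    extract_sustained_flights,
    first_sustained_flight,
    route_lengths,
)
from .segmentation import SegmentationConfig, summarize_individual
from .stats import GroupSample, ProportionPair, kruskal_wallis, proportion_test
from .track_builder import build_tracks, transitions

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("coasttrack")

GROUP_VARIABLES = [
    "initial_stopover_days",
    "along_track_stopover_days",
    "days_at_study_area",
    "progress_km",
    "detour_km",
    "daily_mean_speed_km_per_day",
]


@dataclass(frozen=True)
class RunConfig:
    detections_path: str
    receivers_path: str
    deployments_path: str
    out_dir: str
    filter_cfg: FilterConfig = FilterConfig()
    seg_cfg: SegmentationConfig = field(default_factory=SegmentationConfig)
    routing_cfg: RoutingConfig = field(default_factory=RoutingConfig)
    log_level: str = "INFO"


def _individual_table(tracks, registry, seg_cfg, routing_cfg) -> pd.DataFrame:
    rows = []
    for track in tracks:
        summary = summarize_individual(track, registry, seg_cfg)
        trs = transitions(track, registry, seg_cfg.flight_speed_max_mps)
        season = track.deployment.season
        route = route_lengths(trs, season, routing_cfg, tag_id=track.tag_id)
        has_route = any(not t.simultaneous for t in trs)
        flights = extract_sustained_flights(track, registry, routing_cfg)
        first = first_sustained_flight(flights)
        label = (
            classify_offshore(first, season, registry, routing_cfg).value if first else ""
        )
        rows.append(
            {
                **asdict(summary),
                "progress_km": route.progress_km,
                "detour_km": route.detour_km,
                "has_route_data": has_route,
                "took_detour": route.took_detour,
                "n_sustained_flights": len(flights),
                "first_sustained_flight_label": label,
            }
        )
    return pd.DataFrame(rows)


def _group_summary(indiv: pd.DataFrame) -> pd.DataFrame:
    rows = []
    pairs = [(s, v) for s in indiv["season"].unique() for v in GROUP_VARIABLES]
    for season, variable in pairs:
        season_df = indiv[indiv["season"] == season]
        groups = []
        stats_by_species = {}
        for species, sdf in season_df.groupby("species"):
            vals = sdf[variable].dropna().to_numpy(dtype=float)
            if vals.size:
                q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
                stats_by_species[species] = (med, q25, q75, vals.size)
                groups.append(GroupSample(str(species), tuple(vals)))
        kw_stat = kw_p = None
        if len(groups) >= 2 and sum(len(g.values) for g in groups) >= 3:
            res = kruskal_wallis(groups)
            kw_stat, kw_p = res.statistic, res.p
        for species, (med, q25, q75, n) in stats_by_species.items():
            rows.append(
                {
                    "variable": variable,
                    "season": season,
                    "species": species,
                    "n": n,
                    "median": med,
                    "q25": q25,
                    "q75": q75,
                    "kw_chi2": kw_stat,
                    "kw_p": kw_p,
                }
            )
    return pd.DataFrame(rows)


def _prop_row(name, ga, gb, k1, n1, k2, n2) -> dict:
    row = {
        "comparison": name,
        "group_a": ga,
        "group_b": gb,
        "k1": k1,
        "n1": n1,
        "k2": k2,
        "n2": n2,
        "chi2": None,
        "df": None,
        "p": None,
    }
    if n1 >= 1 and n2 >= 1:
        try:
            res = proportion_test(ProportionPair(k1, n1, k2, n2))
        except ValueError:
            return row
        row.update(chi2=res.statistic, df=res.df, p=res.p)
    return row


def _proportion_tests(indiv: pd.DataFrame) -> pd.DataFrame:
    rows = []
    species_list = sorted(indiv["species"].unique())
    seasons = [s.value for s in Season if s.value in set(indiv["season"])]

    def counts(mask_col, species, season) -> tuple[int, int]:
        sub = indiv[(indiv["species"] == species) & (indiv["season"] == season)]
        if mask_col == "took_detour":  # detours only defined with route data
            sub = sub[sub["has_route_data"]]
        if mask_col == "offshore":
            sub = sub[sub["first_sustained_flight_label"] != ""]
            return int((sub["first_sustained_flight_label"] == "offshore").sum()), len(sub)
        if mask_col == "has_initial":
            return int(sub["initial_stopover_days"].notna().sum()), len(sub)
        return int(sub[mask_col].sum()), len(sub)

    # between species, within season
    for season in seasons:
        for col, name in [
            ("has_initial", "initial_stopover_recorded"),
            ("has_along_track_stop", "along_track_stopover"),
            ("offshore", "offshore_flight"),
        ]:
            if len(species_list) == 2:
                a, b = species_list
                k1, n1 = counts(col, a, season)
                k2, n2 = counts(col, b, season)
                rows.append(_prop_row(f"{name}:{season}", a, b, k1, n1, k2, n2))
    # between seasons, within species
    if len(seasons) == 2:
        s1, s2 = seasons
        for species in species_list:
            for col, name in [("took_detour", "detour"), ("offshore", "offshore_flight")]:
                k1, n1 = counts(col, species, s1)
                k2, n2 = counts(col, species, s2)
                rows.append(_prop_row(f"{name}:{species}", s1, s2, k1, n1, k2, n2))
    # between species, pooled seasons (offshore)
    if len(species_list) == 2:
        a, b = species_list
        ka = na = kb = nb = 0
        for season in seasons:
            k, n = counts("offshore", a, season)
            ka, na = ka + k, na + n
            k, n = counts("offshore", b, season)
            kb, nb = kb + k, nb + n
        if na and nb:
            rows.append(_prop_row("offshore_flight:pooled", a, b, ka, na, kb, nb))
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns paths of the written artifacts."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    registry = read_receivers(cfg.receivers_path)
    deployments = read_deployments(cfg.deployments_path)
    raw = read_detections(cfg.detections_path, registry)
    log.info("input detections: %d", len(raw))
    kept = filter_false_positives(raw, cfg.filter_cfg)
    log.info("post-filter detections: %d", len(kept))

    paths: dict[str, Path] = {
        "individual_summary": out / "individual_summary.csv",
        "group_summary": out / "group_summary.csv",
        "proportion_tests": out / "proportion_tests.csv",
        "manifest": out / "manifest.json",
    }

    if kept:
        tracks = build_tracks(kept, deployments)
        log.info("tracks: %d", len(tracks))
        indiv = _individual_table(tracks, registry, cfg.seg_cfg, cfg.routing_cfg)
        group = _group_summary(indiv)
        props = _proportion_tests(indiv)
    else:
        log.warning("no detections after filtering; writing empty summaries")
        indiv = pd.DataFrame(
            columns=[
                "tag_id",
                "species",
                "season",
                "initial_stopover_days",
                "initial_stopover_minimum",
                "along_track_stopover_days",
                "has_along_track_stop",
                "days_at_study_area",
                "daily_mean_speed_km_per_day",
                "progress_km",
                "detour_km",
                "has_route_data",
                "took_detour",
                "n_sustained_flights",
                "first_sustained_flight_label",
            ]
        )
        group = pd.DataFrame(
            columns=["variable", "season", "species", "n", "median", "q25", "q75", "kw_chi2", "kw_p"]
        )
        props = pd.DataFrame(
            columns=["comparison", "group_a", "group_b", "k1", "n1", "k2", "n2", "chi2", "df", "p"]
        )

    indiv.to_csv(paths["individual_summary"], index=False)
    group.to_csv(paths["group_summary"], index=False)
    props.to_csv(paths["proportion_tests"], index=False)

    cfg_dict = {
        "detections_path": cfg.detections_path,
        "receivers_path": cfg.receivers_path,
        "deployments_path": cfg.deployments_path,
        "filter": asdict(cfg.filter_cfg),
        "segmentation": asdict(cfg.seg_cfg),
        "routing": asdict(cfg.routing_cfg),
    }
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_detections_input": len(raw),
        "n_detections_kept": len(kept),
        "n_individuals": int(indiv.shape[0]),
        "versions": {
            "coasttrack": __import__("coasttrack").__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
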