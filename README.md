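# coasttrack

Analysis pipeline for automated radio-telemetry (Motus-style) detection data
of migrating songbirds along a coastline: track assembly, behavioral
segmentation (initial stopover / along-track stopover / flight / unknown),
sustained-flight extraction with offshore-vs-alongshore routing
classification, progress/detour decomposition, and the nonparametric
statistics used to compare species and seasons. A synthetic-data module
generates detection tables with known ground truth (two archetypes: a
diurnal migrant flying around sunrise and a nocturnal migrant departing in
the first quarter of the night) so the whole pipeline is testable without
any field data.

## Package layout

| module                     | contents                                                              |
| -------------------------- | --------------------------------------------------------------------- |
| `coasttrack.geo_solar`     | haversine distance, great-circle bearing, NOAA sunrise/sunset, night-fraction time axis (0 = sunset, 1 = sunrise) |
| `coasttrack.detections_io` | CSV readers/writers for detection, receiver and deployment tables; false-positive score filter (default threshold 0.67, drop if >=) |
| `coasttrack.track_builder` | per-individual tracks; inter-receiver transitions with distance, ground speed, bearing and a simultaneous-detection flag (> 26 m/s) |
| `coasttrack.segmentation`  | initial-stopover rule (20 km release radius, 2.6 km receiver cluster), behavioral classification (> 1 h dwell -> stopover; < 35 min visit, 5-26 m/s, simultaneous -> flight; slow within 3 d / < 32 km -> stopover; residual -> unknown), per-individual summary metrics |
| `coasttrack.routing`       | seasonal progress sectors (spring 315->90 deg through north, autumn 135-270 deg), cumulative progress/detour lengths, sustained flights (>= 4 spread receivers or a >= 35 km pair, gaps < 7 h), offshore/alongshore classification (island receiver or the 54.135 degN / 8.08 degE corridor rule) |
| `coasttrack.stats`         | tie-corrected Kruskal-Wallis, two-sample equal-proportions chi-square with capped continuity correction, type-7 quantiles, median +/- mean absolute deviation |
| `coasttrack.synthetic_data`| seeded simulator: two-leg coastal receiver array with an island site, waypoint flights, stopovers, detection thinning, injected false positives, full ground-truth records |
| `coasttrack.pipeline` / `coasttrack.cli` | end-to-end orchestration and the `coasttrack` command |

## CLI

```bash
# synthetic dataset with ground truth
coasttrack simulate --seed 42 --birds 8 --out data/

# full pipeline: per-individual summary, group summaries, proportion tests, manifest
coasttrack run --detections data/detections.csv --receivers data/receivers.csv \
               --deployments data/deployments.csv --out results/

# individual stages
coasttrack segment ... --out results/   # per-segment labels
coasttrack route   ... --out results/   # sustained flights
coasttrack stats --individual-summary results/individual_summary.csv --out results/
```

All thresholds can be overridden from a YAML file passed via `--config`:

```yaml
filter:
  fp_threshold: 0.67
segmentation:
  stop_dist_max_km: 32
routing:
  sustained_gap_max_h: 7
```

## Conventions and caveats

* All timestamps are UTC; naive inputs are assumed UTC, epoch seconds accepted.
* The false-positive threshold drops rows with score **>= 0.67** (keeping
  unscored and recapture rows); whether the boundary belongs to the keep or
  drop side is a documented choice, configurable via `FilterConfig`.
* Single-receiver dwells between 35 min and 1 h are labeled `unknown`: they
  are covered by neither the short-visit flight rule nor the stopover rule.
* `days_at_study_area` is a calendar-date difference (whole days); the
  daily-mean-speed denominator is the summed movement-transition time
  rounded up to whole days (minimum 1).
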