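# rmtrack

Trajectory analysis of **neutrophil reverse migration** around a sterile
injury in a microphysiological system (MPS).

Live imaging of an organ-on-chip injury model yields 2D cell tracks:
neutrophils leave an endothelial lumen, migrate toward a circular injury
spheroid, dwell there, and some subsequently migrate away again
(*reverse migration*, rM). `rmtrack` turns raw tracker exports into the
quantities that characterise this behaviour:

* **Alignment** — translate all coordinates so the injury spheroid sits
  at the origin: x_new = x_cell − x_sp, y_new = y_cell − y_sp.
* **Kinematics** — per-step distances dist_i = √((x_{i−1}−x_i)² +
  (y_{i−1}−y_i)²) and velocities dist_i/Δt, in µm and minutes.
* **Contact & segmentation** — a cell contacts the injury site when
  √(x_i² + y_i²) ≤ radius; each contacting track splits into three
  contiguous segments: *approach* (before first contact), *within*
  (first through last contact), *reverse* (after the last exit, no
  re-entry).
* **rM classification** — contact, followed by a final exit of ≥ 2
  points, optionally by a minimum radial travel beyond the radius.
* **Track straightness** — str = disp / d_total per segment, 1 =
  perfectly straight.
* **Location heatmaps** — 2D Gaussian KDE of cell positions with
  per-dimension Scott's-rule bandwidths h_j = σ_j · n^(−1/6).
* **Synthetic cohorts** — a biased persistent random-walk generator that
  emulates lumen exit → directed approach (~4 µm/min) → slow dwell →
  reverse escape, with ground-truth labels, so the whole pipeline is
  testable without access to imaging data.

## Worked example

```python
from rmtrack import (SimulationParams, simulate_trackset,
                     classify_reverse_migrated, cohort_segment_metrics)

params = SimulationParams(n_cells=200, n_frames=240, p_rm=0.3, seed=1)
ts, truth = simulate_trackset(params)          # labelled synthetic cohort
labels = classify_reverse_migrated(ts)         # rM label per cell
metrics = cohort_segment_metrics(ts)           # one row per (cell, segment)

print(sum(labels.values()), "reverse-migrated of", len(ts))
print(metrics.groupby("segment")[["mean_velocity", "straightness"]].mean())
```

prints

```
49 reverse-migrated of 200
          mean_velocity  straightness
segment
approach       4.006804      0.933741
reverse        3.972170      0.934064
whole          2.790298      0.432953
within         1.996258      0.205643
```

Cells approach the injury at ~4 µm/min with high directionality
(straightness ≈ 0.93), slow to half speed and wander while at the site
(straightness ≈ 0.21), and the 49 reverse migrators escape about as fast
and as straight as they arrived — the forward/reverse symmetry that
motivates comparing the two phases. The labels agree with the
generator's ground truth for all 200 cells.

The same steps run as a narrative analysis in `analysis/` (simulate →
classify → per-segment kinematics → density heatmaps; tables land in
`results/`), and from the shell:

```bash
rmtrack simulate --radius 50 --out tracks.csv --truth truth.json
rmtrack analyze --tracks tracks.csv --pixel-size 1 --frame-interval 1 \
        --radius 50 --out metrics.csv --labels labels.json
rmtrack density --tracks tracks.csv --pixel-size 1 --frame-interval 1 \
        --radius 50 --segment within --out density.csv --png heatmap.png
rmtrack all --seed 1 --out-dir run1    # full pipeline + summary.json
```

Real tracker exports are read with `read_tracks(path, pixel_size=...,
frame_interval=..., dialect=ColumnDialect(...))`; pixel size and frame
interval are mandatory acquisition facts with no default.

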