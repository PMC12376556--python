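# Methods

## The analysis problem

In a sterile-injury microphysiological system (MPS), neutrophils exit an
endothelial lumen, migrate through a collagen matrix toward a circular
injury region (a heat-killed cell spheroid), interact with it, and a
subpopulation subsequently migrates away again — *reverse migration* (rM).
The input to this package is not imagery but the track tables that manual
or automatic trackers export: one row per (cell, frame) with pixel
coordinates, plus three acquisition facts the tables themselves do not
carry — the frame interval (min), the pixel size (µm/px), and the injury
spheroid's center and radius in the image frame. Neither the frame
interval nor the pixel size has a default: they are instrument settings
the analyst must supply.

## Coordinate alignment

All analysis runs in a spheroid-centered frame: every point is translated
by minus the spheroid center, so the injury site sits at the origin and a
cell's radial distance is simply √(x² + y²). Translation preserves all
inter-point distances, so every kinematic statistic is identical in the
raw and aligned frames; the aligned frame is used because contact and
escape are radial statements there.

## Kinematics

For a track with points (x_i, y_i) at frames f_i:

* step distance: dist_i = √((x_{i−1}−x_i)² + (y_{i−1}−y_i)²), the
  Euclidean chord between consecutive *recorded* points;
* step velocity: dist_i divided by the elapsed time (f_i − f_{i−1}) ×
  frame_interval. A gap of g frames (missed detections) therefore
  contributes one chord over g frame intervals — positions are never
  interpolated, because interpolation would fabricate observations;
* segment totals: d_total = Σ dist_i over a segment, disp = distance
  between the segment's first and last points, straightness
  str = disp / d_total ∈ [0, 1] (1 = perfectly straight, 0 = closed
  loop). On a zero-length path str is reported as NaN with an explicit
  flag rather than forced to 0 or 1 — both limits are defensible and the
  choice is left to the analyst;
* a segment's mean velocity is by default the unweighted mean of its
  per-step velocities. Whether a figure-style "average velocity" should
  instead be segment distance over segment duration is a convention, not
  a derivable fact; the alternative is exposed as
  `velocity_convention="distance_over_duration"`. The two coincide on
  gap-free tracks.

## Contact, segmentation, and the rM label

A point is in contact with the injury site when √(x_i² + y_i²) ≤ radius,
boundary inclusive, evaluated on recorded points only (chords crossing
the boundary between frames do not count — contact is a per-slice
statement). With F the contact index set, each contacting track is
partitioned into three contiguous segments:

* **approach**: indices < min(F);
* **within**: indices in [min(F), max(F)] — temporary excursions outside
  the radius between first and last contact are absorbed here, because
  the reverse segment is defined from the *last* exit with no re-entry,
  leaving mid-dwell excursions to the within segment by elimination;
* **reverse**: indices > max(F).

A never-contacting track is entirely approach. A track whose first point
is already inside the radius simply has an empty approach segment; it
remains eligible for the rM label.

A cell is labelled reverse-migrated when (i) it contacted the site,
(ii) its reverse segment has at least two points (a single post-exit
point cannot evidence migration), and (iii) its final radial distance
exceeds the radius by at least `min_reverse_displacement` (µm). The
default is 0 — the operational contact-and-exit definition. The stricter
"travelled away for a minimum distance" reading is qualitative with no
canonical value, so it is a parameter, not a constant; the rM set shrinks
weakly as the threshold grows.

## Location heatmaps

Cell-location density is a 2D Gaussian kernel density estimate with a
*diagonal* product kernel: f(g) = (1/n) Σ_i N(g_x−x_i; h_x)·N(g_y−y_i; h_y),
with Scott's-rule bandwidths per dimension, h_j = σ_j · n^(−1/6)
(σ_j the sample standard deviation with the n−1 denominator, the
conventional choice for Scott's rule). The diagonal form — rather than
the full-covariance variant — keeps the estimator the minimal 2D
extension of the scalar-bandwidth formula; it makes the field exactly
translation-equivariant and axis-scale-equivariant, and it integrates to
one. A dimension with zero spread borrows the other dimension's
bandwidth; if both are degenerate (n < 2 or all points coincident) the
estimate is refused with a degenerate-data error rather than silently
regularised. The default evaluation grid is the data bounding box padded
by 3 bandwidths at 128 × 128 nodes (a desk-scale resolution/
normalisation trade-off); normalisation checks use a 5-bandwidth pad.
By default the KDE pools **all** track points; pooling only final
positions is exposed as an option, since either reading of "cell
location" is defensible.

## Synthetic cohort generator

Because the imaging-derived track data are not deposited, validation
runs on a synthetic cohort with known ground truth. The generator is a
biased persistent random walk over the MPS geometry, one step per frame:

* **Start**: on the lumen line at x = center_x − lumen_offset, y normally
  jittered around center_y with sd equal to one spheroid radius (so the
  cohort spans a realistic arc of approach directions).
* **Step length**: speed × frame_interval, speed drawn per step from a
  normal truncated at zero (rejection sampling), times
  `within_speed_factor` while the cell is inside the radius.
* **Heading**: the persistence-weighted circular mean (vector average of
  unit headings) of the previous heading and the current target, plus
  Gaussian noise. The target is the spheroid center during approach, a
  fresh uniform angle during dwell/residence, and a fixed escape
  direction during reverse — straight back toward the lumen (−x) in
  `toward_lumen` mode, a uniform random angle drawn once at escape onset
  in `random` mode.
* **Dwell and fate**: on first contact the cell dwells for a geometric
  number of frames (mean `dwell_frames_mean`; geometric because no
  dwell-time distribution is measurable from the source data and
  memorylessness is the minimal assumption), then reverse-migrates with
  probability `p_rm` or keeps moving unbiasedly inside for the rest of
  the recording. Dwell/resident motion is **confined** to the spheroid:
  a step that would leave the radius has its heading re-drawn (up to 100
  tries, then pointed at the center), preserving the step length
  exactly. Confinement is what makes the ground-truth label clean — a
  non-escaping cell never drifts out and masquerades as rM — and the
  exact step length keeps the noiseless within-segment velocity equal to
  within_speed_factor × speed_mean to machine precision.

Ground truth records, per cell, whether it entered reverse mode and
actually left (the rM label), the first frame inside the radius and the
last frame inside. Randomness is a pure function of the parameters: each
cell consumes its own stream seeded by (seed, cell index), so enlarging
the cohort appends cells without reshuffling existing ones.

### Default study conditions

| parameter | default | unit | rationale |
|---|---|---|---|
| n_cells | 30 (drivers use 200) | — | 3 fields of view × ~10 tracked cells; drivers use a larger cohort for stable statistics |
| n_frames | 180–240 | frames | 3–4 h of imaging at 1 frame/min |
| frame_interval | 1 | min | typical live-imaging cadence for neutrophil chemotaxis; the instrument value is not derivable from track tables |
| spheroid radius | 50 | µm | a ~100 µm injury spheroid |
| lumen_offset | 250 | µm | lumen-to-injury distance at which an approach takes ~1 h |
| speed_mean / speed_sd | 4 / 1 | µm/min | the 3–5 µm/min range observed for neutrophils in this MPS |
| within_speed_factor | 0.5 | — | markedly slower motion at the injury site |
| persistence | 0.6 | — | strongly persistent but noticeably wiggly approach paths (straightness ~0.93) |
| heading_noise_sd | 0.3 | rad | same |
| dwell_frames_mean | 15 | frames | brief interaction relative to the recording |
| p_rm | 0.3 | — | a substantial reverse-migrating subpopulation |

### What the generator does and does not emulate

It reproduces the three observed behaviours — persistent directed
approach, slow confined dwell, and reverse escape toward the lumen or in
a random direction — with realistic speeds and track lengths, which is
what the contact classifier, the segment partition and the kinematic
statistics actually consume. It does **not** model chemokine gradients,
endothelial transmigration mechanics, cell–cell interaction, tracking
errors (misses, identity swaps) other than optional frame gaps, or 3D
motion (the tracking and all the formulas here are 2D). Passing tests
therefore demonstrate correctness of the *measurement pipeline* on
tracks with known structure, not biological fidelity of any particular
parameter value.

## Numerical choices

* Contact uses ≤ (boundary counts as contact).
* Straightness of a noiseless straight approach equals 1 to ~1e-12 (the
  residual is floating-point, from circular-mean round-trips).
* Truncated-normal speeds are drawn by rejection; with speed_sd = 0 the
  draw is the constant mean, making noiseless limits exact.
* Metrics CSVs print full float repr, so tables round-trip well below
  1e-9 relative error.
* Group comparisons (Mann-Whitney, t, one-way ANOVA) delegate to
  scipy.stats; error bars in reports are SEM; significance labels:
  ns (p ≥ 0.05), * (< 0.05), ** (< 0.01), *** (< 0.001).

## Problem sizes

Cohort analyses in the tests and drivers use 100–500 cells × 120–240
frames — comfortably above the scale of a manually tracked experiment
(tens of cells) while keeping every suite run and the acceptance script
in seconds on one CPU.

## Known limitations

* Contact is point-wise; a cell crossing the boundary and back within a
  single frame interval is never seen in contact.
* The rM definition depends on the recording ending after the final
  exit; a cell still inside at the last frame is not rM by construction,
  even if it would have left.
* The diagonal-bandwidth KDE under-smooths along directions of strong
  correlation between x and y; the full-covariance variant is
  deliberately out of scope.
* The classifier is deterministic given the geometry; uncertainty in the
  spheroid center/radius propagates directly and is not modelled.
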