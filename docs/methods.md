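# Methods

## Problem and model

The package converts pose-estimation keypoint time series into behavior-code
timelines. The underlying assumption is that *instantaneous posture* — the
geometric configuration of a few keypoints within one frame — carries enough
information to distinguish the behavioral states of interest, so that a
per-frame feature vector, embedded into 2-D and clustered, recovers those
states. No temporal model is fitted; time enters only through thinning and
through the hold-forward expansion of thinned labels.

All geometry is computed in raw image coordinates: origin at the top-left
corner, x right, y down, units pixels, frames indexed from 0, timestamps
`frame / fps × 1000` ms. Because y points down, the scalar cross product
`u_x v_y − u_y v_x` follows a left-handed sign convention (positive when the
second vector lies clockwise of the first as seen on screen). Cross products
are reported in raw px² — they are deliberately *not* normalized by vector
lengths at the feature stage, so that the magnitude (how far apart the
keypoints are) is preserved; scaling questions are handled later by min–max
normalization, matching the pipeline order featurize → mix/norm → embed.

## Features

| feature | arity | definition | units |
|---|---|---|---|
| position_x / position_y | 1 | raw coordinate | px |
| speed | 1 | backward difference `‖p_t − p_{t−1}‖ / Δt` | px/s |
| distance | 2 | `‖b − a‖` | px |
| dot_product | 3 (o, a, b) | `(a−o)·(b−o)` | px² |
| cross_product | 3 (o, a, b) | `(a−o)×(b−o)` scalar | px² |

Speed uses backward differences with frame 0 missing — the simplest contract
consistent with "displacement per unit time", and documented so users can
shift by one frame if they need centered estimates. When frames are missing
(e.g. after scene filtering), Δt is the actual elapsed time between retained
frames. Coincident keypoints give dot/cross = 0 rather than an error;
transient keypoint overlap is common in real tracks.

Missingness is strict: any feature touching a NaN coordinate is NaN. Ingest
never drops low-confidence detections; `filter_confidence(track, thr)` is
the explicit, separate step that masks them.

The right-arm preset encodes four cross products over left shoulder (5),
right shoulder (6), right elbow (8) and right hand (10), with origins 5, 10,
6 and 8 respectively (`shoulder_left`, `hand`, `shoulder_right`, `elbow`),
and the desk-task preset prepends the neck (18) x-position. Together these
five series separate lateral trunk sway from arm configuration.

## Dwell-density maps

`kde_dwell` evaluates a Gaussian product-kernel mixture (one kernel per
non-missing observation, per-axis bandwidths in px) at the centers of a
regular raster. The default bandwidth is Silverman's rule per axis,
`1.06 σ n^{−1/5}`, falling back to 1 px for degenerate (zero-variance) axes.
The default extent is the frame size when known, else the data bounding box
padded by 4 bandwidths — wide enough that the discrete bin-weighted sum
approximates 1. The evaluation is hand-written (a separable outer product)
because the per-axis fixed pixel bandwidth on a fixed raster is not what
generic KDE helpers expose.

## Mix/Norm conventions

Min–max maps each column independently to [0, 1] over its non-missing
values; a constant column maps to all zeros (with a logged warning) rather
than NaN, so embedding input stays finite. Binarize uses `x ≥ threshold → 1`
(ties go to 1). Division by zero yields missing, with a logged count.
Concatenation aligns series on the intersection of frame indices — an inner
join — because thinning and scene filters legitimately desynchronize series;
dropped row counts are logged.

## Scenes

Scenes are half-open `[start_ms, end_ms)` intervals so adjacent scenes
compose without double-counting boundary frames. Filtering is type-generic
(tracks or feature series) because whether scene selection is applied before
or after featurization is an analysis choice, not a pipeline constraint.

## Thinning, embedding, clustering

Thinning keeps rows at positions 0, k, 2k, … of the row sequence; at
29.97 fps and k = 5 that is one row per ≈ 0.17 s. Its purpose is to remove
transitional frames — intermediate postures between one held posture and the
next — which otherwise blur cluster boundaries in the embedding.

The embedding is UMAP, always to two dimensions, with `n_neighbors = 20` and
`min_dist = 0.1` as defaults (values around 20–50 work well for posture
data; the config and CLI take the value explicitly rather than switching
silently). Rows with any missing selected feature are dropped before
embedding — distance computations need complete vectors — and excluded from
the point-to-frame provenance. The random seed is fixed (default 42,
recorded in the provenance sidecar); with a fixed seed UMAP runs
single-threaded and reruns are bit-identical.

Manual clustering is replayed headlessly: each pick is (u, v, radius,
cluster), the radius measured in **embedding coordinate units** — a headless
tool has no screen pixels, so interactive picker ranges quoted in GUI pixels
do not transfer numerically. Later picks overwrite earlier labels.
Automatic clustering uses k-means when the cluster count is known and
HDBSCAN otherwise, with `min_cluster_size = max(5, n_points // 50)` (2 % of
the points): scale-invariant, small enough to keep rare postures, large
enough to ignore stray transitional points. HDBSCAN's noise points stay
unassigned and code as `NONE` in the timeline.

## Timeline construction

Thinned cluster labels are expanded to full frame rate by hold-forward: each
coded point governs the frames from its own source frame up to (not
including) the next retained source frame; frames before the first retained
frame, and spans governed by unassigned points, get `NONE`. Hold-forward is
the simplest order-preserving gap rule consistent with presenting a
continuous coded time series after thinning. The per-frame export
(`frame,time_ms,code`) and the run-length interval export
(`code,start_ms,end_ms`, half-open) are mutually convertible without loss.

## Synthetic generator

The generator emulates what a keypoint detector produces for a seated person
holding a sequence of postures: K templates (keypoint → mean position), a
first-order Markov chain over templates sampled per frame, and independent
isotropic Gaussian jitter per coordinate standing in for detector noise.
The default desk-task spec has five regimes over the Halpe-26 upper-body
subset (ids 5, 6, 8, 9, 10, 18) — reaching left, hand raised, hand near the
face, reaching right, and using the left hand with the right arm tucked —
with defaults chosen once as realistic study conditions: 385 s at 29.97 fps
(≈ 11 538 frames, mirroring a ~6.5-minute task video), `noise_sd = 3` px
(typical detector jitter at 640×480), and `stay_prob = 0.983` per frame
(mean dwell ≈ 2 s).

What the generator does **not** emulate: continuous motion between postures
(switches are instantaneous, so there are no genuinely transitional frames),
occlusion and detection dropouts, confidence degradation, multi-person
interaction, or camera motion. Passing tests therefore demonstrate that the
pipeline machinery is correct and that well-separated instantaneous postures
are recovered; they do not certify performance on real video, where
transitional postures, tracking noise and ID swaps make both thinning and
clustering genuinely harder.

## Agreement metric

Cluster names are arbitrary, so a coded timeline is scored against the true
ethogram by first solving a maximum-overlap one-to-one assignment between
codes and regimes (Hungarian algorithm on the contingency table), then
computing per-frame agreement. Frames within `thin_step` frames after a true
regime change are excluded: the hold-forward rule cannot know about a change
until the next retained frame, so those frames measure the thinning
granularity, not clustering quality. `NONE` frames count as disagreement.

## Numerical and design notes

- Track/feature containers are Parquet payloads with JSON metadata; float64
  round trips are bit-exact and NaN placement is preserved.
- DeepLabCut bodyparts map to keypoint ids via a user-supplied name→id table
  when given, else 0..n−1 in column order; the mapping used is recorded in
  the track's provenance attributes. fps is required caller input (the
  dialect does not store it).
- The pipeline is a pure function of (inputs, config, seed); reruns are
  byte-identical, which the test suite asserts on the full artifact set.
- Degenerate inputs raise typed errors early (empty scene tables, too few
  rows for the neighbor count, k larger than the point count), and
  `validate_track` reports violations without raising.

## Problem sizes used in the automated checks

The acceptance script runs the ten-seed pipeline at the generator's default
385 s duration (≈ 2 300 embedded points per seed); determinism checks use a
30 s recording, and geometry oracles use 1 000 random triples. These sizes
are the package's own choice of a thorough-but-quick standard benchmark.

## Known limitations

Single-person analysis per run (multi-person tracks must be split first; ID
swaps are not repaired); 2-D embeddings only; no joint-angle or 3-D
features; no automated action (movement-sequence) classification — the
method codes instantaneous posture.
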