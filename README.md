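# crustavision

A low-power deck-camera video pipeline for counting and landmarking crabs
and lobsters in fisheries electronic monitoring, with a seeded synthetic
data generator that makes every stage testable offline.

The pipeline turns a video into one record per presented animal:

1. **Temporal segmentation** — a cheap per-frame presence classifier emits a
   volatile confidence signal; two rectangular smoothing passes interleaved
   with step thresholds (defaults 20 / 0.01 / 10 / 0.5) extract "contigs",
   maximal intervals each attributed to one animal.
2. **Frame selection** — a per-view scorer rates every in-contig frame for
   representativeness (centrality, scale, blur); the per-contig, per-view
   argmax is shortlisted.
3. **Detection & cropping** — a pluggable detector localises the animal on
   the selected full-resolution frame; a dataset-wide fixed crop size (mean
   bbox dimensions) cuts an undistorted ROI by pure pixel copy — nothing on
   the measurement path is ever resampled.
4. **Keypoint regression** — 7 named landmarks (`crab_left`, `crab_right`,
   `left_eye`, `right_eye`, `carapace_end`, `tail_end`, `last_segment`) are
   regressed as a 14-vector in crop pixel coordinates; Mean Euclidean Error
   and size-relative error are the evaluation metrics.

A GPS scheduler decides record-vs-process mode (4-knot threshold plus a
port geofence), and the `synthetic` module renders annotated blob "animals"
with full ground truth (presence, view, bbox, keypoints, quality) so the
whole flow runs without real footage. The trainable stages (frame scorer,
keypoint regressor) are small numpy MLPs on block-pooled pixel features —
no deep-learning framework required.

## CLI

```bash
crustavision simulate --out scratch/vid --events 5 --seed 1   # synthetic video
crustavision segment --signal scratch/vid/signal.csv --out scratch/contigs.csv
crustavision run --video scratch/vid --out scratch/out        # full pipeline
crustavision train-scorer --out scratch/scorer.npz
crustavision train-keypoints --out scratch/kp.npz
crustavision evaluate --contigs scratch/contigs.csv \
    --schedule scratch/vid/schedule.csv --n-frames 810
```

`run` writes `records.csv` (one row per contig: bounds, selected frame per
view, class, keypoints), `selected_frames.csv`, and a `manifest.json` with
the config hash, seed and per-stage frame counts. Runs are deterministic
for a fixed seed.

## Layout

| Module | Role |
| --- | --- |
| `crustavision.synthetic` | seeded signals, frames, videos + ground truth |
| `crustavision.preprocess` | greyscale, area downscale, augmentation chain |
| `crustavision.segmentation` | smoothing chain, contig extraction, scoring |
| `crustavision.selection` | frame scorers, per-contig argmax, pairwise accuracy |
| `crustavision.detection` | detector contract + mock, crop-size derivation, ROI crop |
| `crustavision.keypoints` | landmark regressor, MEE / relative error, VIA import |
| `crustavision.scheduler` | haversine speed, record/process state machine |
| `crustavision.pipeline` | end-to-end orchestration, per-stage profiling |
| `crustavision.cli` | `crustavision` command-line entry point |
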