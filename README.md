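# kinemetry

Joint-angle estimation from tracked 3D body landmarks, and its validation
against a high-rate optical gold standard.

Low-cost RGB-D cameras (Kinect V2, Orbbec Astra, Intel RealSense) and
RGB-only pose trackers (MediaPipe) report per-frame 3D positions of human
body joints. Whether the joint angles derived from those skeletons are
accurate enough for clinical range-of-motion assessment is an empirical
question, usually answered by recording the same movement simultaneously
with a marker-based motion-capture system (e.g. Qualisys at 180 Hz) and
comparing the two angle signals. This package implements that whole
comparison pipeline as a reusable, tested library, together with a
synthetic motion generator that stands in for the original recordings —
none of which were ever deposited — so every stage can be exercised and
validated end to end.

## What the pipeline computes

1. **Back-projection** (`kinemetry.camera`). An RGB tracker gives a joint
   as a pixel (x_p, y_p); the depth image gives its range z. Under the
   pinhole model with focal length f and principal point (x_o, y_o):

   x_w = (x_p − x_o)·z/f, y_w = (y_p − y_o)·z/f, z_w = z.

2. **ISB-style joint angles** (`kinemetry.kinematics`). A body-anchored
   orthonormal basis is built per frame: ŷ up the trunk, x̂ the
   hip-to-hip direction orthogonalized against ŷ, ẑ = x̂ × ŷ. Sensor
   vectors change basis via v_bc = B⁻¹ v_sc (B orthonormal, so Bᵀ). The
   monoplanar joint angle is the angle between the moving
   (distal − proximal) segment vector and the plane's reference axis,
   with an out-of-plane tolerance check against the plane normal.

3. **Signal conditioning and synchronization**
   (`kinemetry.signal_pipeline`). Each angle series is low-pass filtered
   (7th-order Butterworth, zero phase; 5 Hz cutoff for 30 Hz streams,
   30 Hz for the 180 Hz stream) and smoothed with a 7-sample moving
   average; the repetition maxima are detected; each series is split
   into start→first-peak, first→last-peak and last-peak→end parts and
   resampled part-by-part onto the gold segmentation with quadratic
   interpolation, which equalizes length and phase across streams.

4. **Agreement statistics** (`kinemetry.stats`). Per sample
   EA = |θ_sensor − θ_gold|; per movement the median EA and
   RMSAE = √(Σxᵢ²/n); accuracy classified against the clinical
   reference CR = 12.78 ± 7.44° (published human goniometry error):
   *excellent* if median+SD < CR, *good* if median < CR, *moderate* if
   median ≤ CR+5°, else *poor*. Pearson r is banded per Portney–Watkins
   (0.5/0.75/0.9). Sensors are compared with Friedman's rank sum and
   pairwise Wilcoxon signed-rank tests ("\*" p < 0.05, "\*\*" p < 0.001).

5. **Bookkeeping** (`kinemetry.io`). Movement codes such as
   `K-FLEX-FR-1` (knee–flexion–frontal–recording 1, dialect variants
   accepted), the recording × volunteer availability grid and the
   lost/analyzed/executions accounting.

The synthetic generator (`kinemetry.synthetic`) scripts raised-cosine
monoplanar movements (default: 90° excursion, 0.25 Hz, 5 repetitions),
poses a rigid skeleton by forward kinematics, renders 2D landmarks +
depth through a virtual pinhole camera at 0° or 30° subject orientation,
and emits a 180 Hz gold stream plus 30 Hz noisy sensor streams with
random start offsets — the conditions the analysis assumes.

## Worked example

The numbered scripts under `analysis/` run the study in stages and write
their outputs under `results/`:

```sh
python analysis/01_simulate_dataset.py        # dual-rate skeleton CSVs
python analysis/02_compute_angles.py          # per-stream angle series
python analysis/03_condition_and_synchronize.py
python analysis/04_validation_report.py       # full synthetic study
python analysis/05_published_aggregates.py    # printed-table reanalysis
```

Stage 03 prints, for each simulated movement, the per-sensor agreement
after synchronization, e.g.:

```
K-FLEX-FR-1 Astra      median AE  1.09 deg, RMSAE  1.67 deg
K-FLEX-FR-1 Intel      median AE  2.33 deg, RMSAE  3.62 deg
K-FLEX-FR-1 Kinect     median AE  2.05 deg, RMSAE  2.70 deg
K-FLEX-FR-1 MediaPipe  median AE  1.63 deg, RMSAE  2.25 deg
```

With 5 mm landmark noise the recovered angles stay within ~1–3° of the
gold stream — i.e. the pipeline itself adds little error, so the much
larger errors reported for real sensors reflect the sensors, not the
analysis. Stage 05 re-derives the published summary rows from the
printed per-movement cells and reproduces the loss accounting
(19/120 recordings lost, 15.83 %, 505 executions analyzed) and the
accuracy labels (MediaPipe *excellent* overall at 8.57 ± 3.06°; Kinect
*good* overall, *moderate* for upper limbs at 16.01 ± 6.72°).

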