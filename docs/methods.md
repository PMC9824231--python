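# Methods

This note records the models, conventions and numerical choices behind
the package, including the points where the design was genuinely open.

## Coordinate conventions

Sensor coordinates follow the image convention: origin at the camera,
x right, y **down**, z away from the camera, metres. Pixel coordinates
have their origin top-left, sub-pixel positions kept as floats; depth
lookup rounds to the nearest integer pixel, falling back to the median
of the valid depths in the 3×3 neighbourhood when that pixel is invalid
(zero/NaN), and flagging the landmark (never silently dropping it) when
none are valid. The flip from image "down" to anatomical "up" happens
exactly once, inside the body-basis construction — the back-projection
itself is the bare pinhole relation and nothing else. Lens distortion
and RGB-to-depth registration are out of scope; frames are assumed
registered.

## Body basis and in-plane angles

The basis is rebuilt per frame from trunk landmarks: ŷ along
mid-spine → spine-top for upper-limb analyses, spine-base → mid-spine
for lower-limb ones (mirroring the trunk construction at pelvis level);
x̂ is the left-hip → right-hip direction Gram–Schmidt-orthogonalized
against ŷ; ẑ = x̂ × ŷ. The result is orthonormal and right-handed by
construction and validated to 1e−9. Collinear landmarks raise a
degenerate-basis error. Because every angle is computed from dot
products in this body frame, the measurement is invariant under rigid
motions of the whole subject (verified to < 1e−6°), which is the reason
the 0° and 30° camera orientations need no special handling.

Planes are defined in body coordinates — frontal (normal ẑ), sagittal
(normal x̂), horizontal (normal ŷ). The reference axis, against which
the angle is measured, is the trunk-down direction −ŷ for the frontal
and sagittal planes, so the anatomical neutral (limb hanging along the
trunk) reads 0° and full elevation 180°, matching range-of-motion
convention; the horizontal plane uses x̂. Out-of-plane tolerance: the
moving vector's angle to the plane normal must be within `tolerance`
of 90°. The default tolerance is 90°, i.e. the check is disabled unless
configured — a strict default would unpredictably reject noisy tracking
data; frames that do fail (or lack joints) become masked gaps, filled
later or escalated.

## Synthetic study conditions

The generator emulates the validation study's acquisition conditions;
its defaults are fixed once and are not tuning knobs:

| parameter | default | rationale |
| --- | --- | --- |
| movement frequency | 0.25 Hz | one repetition per 4 s, typical of guided clinical ROM execution; movements are specified as well under 1 Hz |
| amplitude / baseline | 90° / 10° | large-joint flexion/abduction excursion; a small non-zero resting angle as in practice |
| repetitions | 5 | per recording |
| lead-in / tail | 1.5 s / 2 s | pre- and post-movement hold at baseline |
| gold rate / sensor rate | 180 Hz / 30 Hz | the dual-rate acquisition being validated |
| landmark noise SD | 5 mm (sensors), 0.5 mm (gold) | plausible tracking jitter vs. marker-based accuracy; isotropic Gaussian on 3D positions, since no sensor noise model was ever published |
| start offsets | U[0, 1] s per stream | forces nontrivial synchronization |
| subject distance | 2.5 m | within every sensor's working range; not documented, config knob |
| camera orientation | 0° or 30° about the vertical axis through the pelvis | the two recording positions |
| dropout probability | 0.15 per recording | near the observed 19/120 recording loss rate |

The scripted trajectory is a raised cosine per repetition: it starts
and ends at baseline, has exactly one maximum per repetition (which the
peak-based synchronization requires) and a single spectral line at the
movement frequency (so the 5 Hz low-pass passes it essentially
unchanged). Forward kinematics rotates the moving segment — the distal
joint and everything below it, rigidly — about the plane normal in body
coordinates, preserving segment lengths exactly; the scripted angle is
recovered by the angle computation to < 1e−6°, which is the round-trip
oracle used throughout the tests.

What the generator does **not** model: soft-tissue artifact, body-shape
variation, tracking-model bias (systematic joint-centre offsets),
occlusion-dependent noise, or photorealistic appearance. Passing tests
therefore demonstrate the correctness of the *analysis* — geometry,
angles, filtering, synchronization, statistics — not the accuracy of
any physical sensor; with isotropic 5 mm noise every simulated sensor
lands in the *excellent* band, far better than real devices.

## Signal pipeline choices

- **Zero-phase filtering.** The Butterworth low-pass is applied
  forward-backward (`sosfiltfilt`). The study's filter order and
  cutoffs are kept (order 7; 5 Hz at 30 Hz sampling, 30 Hz at 180 Hz —
  the latter passes most of the band and is retained as specified), but
  causal filtering would delay the 30 Hz and 180 Hz streams by
  different amounts and bias the peak-based synchronization; zero-phase
  application avoids that at the cost of doubling the effective order.
- **Moving average**: kernel 7, edge-reflection padding to preserve
  length. At 0.25 Hz the kernel attenuates the oscillating component by
  ~0.6 % (30 Hz stream), which is the dominant residual in the
  zero-noise end-to-end error (~0.17° median).
- **Gap filling**: linear interpolation across masked runs of ≤ 5
  samples; a longer gap marks the recording lost rather than repaired.
- **Peak detection**: local maxima with prominence ≥ 20 % of the signal
  range and spacing ≥ half a repetition period (period estimated from
  the dominant FFT line when no hint is given). No detection parameters
  were ever published; these make detection scale-free. Each peak is
  refined to sub-sample precision by a parabolic vertex fit — at 30 Hz
  a half-sample timing error on a 90° movement already costs ~1° on the
  flanks, so sample-grid peaks would dominate the error budget.
- **Motion trimming.** Streams start at different offsets, so the
  pre- and post-movement holds have stream-dependent lengths; aligning
  untrimmed series would warp the first rise severely. Before
  alignment, each series is cut to its motion execution at the last
  crossing of baseline + 5 % of range before the first peak (and the
  first after the last peak), with the crossing located to sub-sample
  precision.
- **Interpolation**: "second-order polynomial" is read as a quadratic
  spline — a single global quadratic cannot represent a five-peak
  signal. Each of the three parts is resampled onto the corresponding
  gold part; quadratic interpolation is exact on quadratics (tested to
  1e−9). When source and target grids coincide the samples are copied,
  making identity resampling bit-exact. A part spanning fewer than
  3 samples falls back to linear with a logged warning.
- **Synchronization contract**: equal peak counts across all streams,
  otherwise the recording is flagged lost and enters the availability
  grid as such.

## Statistics conventions

- Summary rows are the arithmetic mean ± **sample** (n−1) standard
  deviation of the per-movement values (medians, RMSAE or r); the
  all-data row pools the upper- and lower-limb per-movement values.
  Sample SD is the convention that reproduces the published summary
  cells from their per-movement cells; population SD does not.
- The *moderate*/*good* boundary of the clinical-reference
  classification uses the median alone (the SD enters only the
  *excellent* criterion) — the variant consistent with the published
  labels.
- Correlations are computed on the synchronized angle series, not on
  error series.
- Friedman blocks are movement executions (one error median per
  execution per sensor, paired across sensors), with Wilcoxon
  signed-rank post hocs; a Shapiro–Wilk pre-check documents the
  non-normality that motivates the rank tests. Identical groups are
  reported as statistic 0, p = 1 (no rank information).

## Published-table reanalysis

`kinemetry.published` embeds the study's printed per-movement cells,
availability grid and summary rows as inputs. Recomputation shows the
lower-limb summary row, both correlation mean rows, the upper-limb RMS
row and the Kinect/MediaPipe columns of the upper-limb and pooled rows
to be internally consistent to one unit in the last printed digit. The
upper-limb (hence pooled) summary cells for Astra and Intel are *not*
derivable from their printed per-movement cells (off by 0.05–0.09°,
indicating a typo in a body cell), and the lower-limb RMS table
duplicates the median table outright; these are excluded from exact
regression and marked as such in the module.

## Problem sizes

Default test and driver runs use one volunteer per recording cell and
one or a few recordings per movement (a full recording is ~22 s of
motion at 180 Hz + 4 × 30 Hz); the statistical machinery is identical
at any scale, and `StudyConfig` scales the layout up to the full
24 recordings × 5 volunteers design when desired.

## Known limitations

- The three-segment alignment assumes every stream captured all
  repetitions; a stream that misses its first repetition entirely is
  rejected (peak-count mismatch) rather than partially aligned.
- Angles are reported in [0°, 180°] about a single plane; full 3-DoF
  Euler/Cardan decomposition and kinetic quantities are out of scope.
- The overlay path samples depth at one (nearest) pixel per landmark;
  real depth maps have edge noise that the sparse synthetic depth
  frames do not exhibit.
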