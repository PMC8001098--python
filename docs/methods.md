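# Methods

## The effort model

A grayscale image is read as a terrain: pixel intensity is elevation over
the image plane.  The descriptor samples `Nk` straight-line trajectories
between independently drawn uniform random pixel pairs (redrawn until the
endpoints are at least 50 px apart, so every "stage" carries a meaningful
amount of terrain), rasterizes each segment, and records the intensities
under it as a 1-D stage profile.  Rasterization samples the segment at
`ceil(length) + 1` equally spaced parameter values and takes the nearest
pixel at each; consecutive duplicates are kept, so profile samples are
uniformly spaced along the segment and the section-distance computation
below can treat the index axis as metrically uniform.

Each profile is cut into `Ns = floor((Ni − 1)/L)` sections of `L` index
steps; section `n` spans indices `(n−1)·L .. n·L`, so sections are
disjoint in steps while sharing their boundary samples, and a trailing
remainder shorter than `L` is dropped.  For a section from `A = (Ax, Ay)`
to `B = (Bx, By)` in the (index, intensity) plane:

- grade fraction `S = (By − Ay)/L`, computed on raw pixel/intensity units;
- gravity `FG = g·sin(arctan S)·m`, rolling `FR = g·cos(arctan S)·m·Cr`,
  total `FT = FG + FR + FA`;
- time `t = d(A, B)/v`, with `d` the Euclidean distance after scaling both
  axes to meters;
- power `P = FT·v`, energy `E = P·t` (equivalently `FT·d`).

Per-trajectory sums `(Pk, Ek)` are averaged arithmetically over the `Nk`
trajectories into the image features `(FE, FP)`.

### Units

The pixel→meter scale assigns the image diagonal — the longest straight
path in a rectangle — a course length of 200,000 m, i.e. a long one-day
road-race course.  The same scale is applied to the intensity axis so the
mixed-axis distance `d` is dimensionally coherent; the grade `S` is a
ratio on raw units, where a common scale would cancel anyway.

### Parameters and defaults

| parameter | default | unit | meaning |
|---|---|---|---|
| `Nk` (`n_trajectories`) | 500 | – | trajectories per image; features stabilize near this count (measured below) |
| `L` (`section_length`) | 2 | px | section length in profile index steps |
| `min_trajectory_length` | 50 | px | minimum endpoint distance |
| `g` | 9.8 | m/s² | gravitational acceleration |
| `m` | 80 | kg | cyclist + bike mass |
| `Cr` | 0.005 | – | rolling-resistance coefficient |
| `v` | 11 | m/s | constant velocity (a typical pro-race average) |
| `FA` | 0 | N | constant air-resistance force |
| `course_length` | 200,000 | m | physical length of the image diagonal |
| `median_kernel` | 5 | px | pre-filter window |
| `background_sigma` | min(h, w)/4 | px | homogenization scale |

`FA` defaults to zero: being constant, a nonzero value only adds
`FA·v·t` per section, i.e. a texture-independent offset to both features,
so it carries no discriminative information.

### Slope handling: why `absolute` is the default

With signed slopes and the Euclidean section distance the model admits an
exact identity.  Since `d = mpu·L·√(1+S²)` and `cos(arctan S) =
1/√(1+S²)`, the rolling term contributes `FR·d = g·m·Cr·mpu·L` per
section — a constant — while the gravity term telescopes,
`Σ FG·d = g·m·mpu·(TP(end) − TP(start))`: descents refund climbs
exactly.  A trajectory's energy then depends on its endpoint intensities
only, and the image energy feature degenerates to a constant plus a
zero-mean fluctuation on any statistically stationary texture — it cannot
separate rough from smooth terrain by location.  (The package's test
suite asserts this identity.)  A roughness descriptor needs effort to
accumulate on descents as well, so by default the grade enters the
gravity term by magnitude (`slope_mode="absolute"`); braking on a steep
descent is effort too.  The literal signed form remains available as
`slope_mode="signed"`, and a `distance_mode="horizontal"` variant
(section distance `L·mpu`, ignoring the intensity axis) is provided since
the section-time definition can be read either way; the default follows
the mixed-axis Euclidean reading.

### Preprocessing

Slope estimates are sensitive to impulsive noise, so images are median
pre-filtered (5×5, edge replication — the output keeps the input shape,
which keeps trajectory geometry simple).  An optional homogenization step
removes very-low-frequency background trends by subtracting a
Gaussian-smoothed background estimate (`sigma = min(h, w)/4` by default)
and re-adding the global mean; any reasonable detrender would do, and the
pipeline exposes it as an on/off switch because downstream performance is
expected to be robust to its presence.  Intensities stay real-valued
after filtering; only the entropy features re-quantize (round + clip to
0..255) before histogramming.

## Entropy baseline

Thirteen features: for each of six patch sizes (50, 100, 150, 200, 250,
300 px squares) the image is tiled with non-overlapping patches anchored
top-left (partial edge patches dropped), Shannon entropy of the 256-bin
gray-level histogram is computed per patch, and the mean and population
variance of those entropies are features; the whole-image scale
contributes its single entropy.  7 scales × 2 statistics would give 14;
the whole-image scale has exactly one patch, whose variance is
uninformative, so it contributes only its entropy — hence 13.  A scale
larger than the image falls back to the whole image as its single patch
(variance 0), keeping the vector complete for inputs between 50 and
300 px.

## Synthetic textures

The generator emulates the relief contrast between benign-like smooth
mucosa and malignant-like vascularized tissue, not their appearance:

- `noise`: white noise smoothed at scale `roughness` px, min–max scaled
  to a peak-to-peak `amplitude` around mid-gray.  One knob (`amplitude`)
  controls slope statistics linearly.
- `vessel`: a bright background (200) carved by `n_vessels` dark sinuous
  strokes — random-phase sinusoids perturbed by a smoothed random walk,
  rendered with a Gaussian cross-profile of width `vessel_width` — at
  depth `amplitude`.
- `flat` and `ramp` exist for closed-form and monotonicity checks.

Default class recipes: smooth = noise with amplitude 10 and roughness 6;
rough = vessels with amplitude 120, 12 vessels of width 3 and wiggle 6.
Datasets assign images to synthetic "patients" (groups) that never
straddle classes, so patient-exclusive splitting can be exercised.

What passing tests on these textures show: that the features respond to
relief amplitude and spatial frequency exactly as the model predicts, and
that the evaluation harness is leak-free and discriminates when the
classes genuinely differ.  What they do not show: performance on real
endoscopic images, whose relief is confounded by illumination, specular
highlights, moisture and anatomy that the generator does not model.

## Evaluation harness

Feature tables are pandas DataFrames (`image_id`, `group_id`, `label`,
then features).  Splitting is by group within each class (each class
keeps at least one group on both sides); leakage is impossible by
construction and asserted on every split.  Four classifiers — polynomial
SVM, RBF SVM, kNN (Euclidean), random forest — are tuned by 10-fold
cross-validated grid search on the training rows; SVM and kNN inputs are
standardized with training statistics inside the pipeline (standard
practice for margin/distance-based models).  The frozen best model is
then applied to the held-out rows in 10 folds and the fold confusion
matrices are pooled — with a frozen model this equals scoring all rows at
once, but the fold protocol is kept explicit.  The `full` grid profile
spans C and γ from 10⁻³ to 10³ in decades, k from 1 to 1000, trees
5..1000 in fives and depth 1..50; the `fast` profile truncates these
(k ≤ 50, trees ≤ 200, coarse depth) for desk-scale runs.  Both contain
the reference optima C = 1, γ = 0.01, k = 10, depth 7 with 60 trees.
kNN candidates exceeding a CV fold's fit size are dropped automatically.

Feature ranking orders features by the p-value of a two-class location
test: Student's t-test, or a rank test.  The rank test defaults to the
rank-sum (Mann–Whitney) form because the class groups are independent;
the literal signed-rank test on samples trimmed to equal length is
available via `paired=True` for fidelity to pipelines that used it on
unpaired data.  Features with an undefined statistic (constant in both
classes) are flagged and ranked last; ties break by feature name so the
ranking is deterministic.

## Numerical choices

- All randomness flows through `numpy.random.default_rng`; dataset and
  table builders spawn per-image seeds from a single `SeedSequence`, so
  every artifact is reproducible bit-for-bit from one integer.
- The production extractor is vectorized over sections; an independent
  naive scalar-loop implementation in the test suite agrees with it to
  better than 1e-9 relative (measured ~1e-15).
- Feature extraction is exactly shift-invariant for integer-valued
  intensity offsets: slopes and section distances depend on intensity
  differences only, and the median filter commutes with shifts.
- Degenerate inputs fail loudly: images smaller than the minimum
  trajectory length, profiles shorter than `L + 1`, even median kernels,
  non-positive smoothing scales, single-class training data and
  class-straddling groups all raise `ValueError`.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use a 300×300 flat image at
the full `Nk = 500` for the closed form; twenty 80×80 random terrains at
`Nk = 100` for oracle agreement (the agreement bound is independent of
problem size); and a 200-image, 20-group benchmark of 150×150 textures at
full defaults for classification and ranking.  On that benchmark the
class-conditional interquartile ranges of FE and FP are disjoint by a
wide margin and kNN classifies the held-out groups essentially perfectly;
Monte-Carlo scatter of FE across independent seeds at `Nk = 500` has a
coefficient of variation of about 3% on a fixed vessel texture (7.5% at
`Nk = 50`), consistent with 1/√Nk averaging.

## Known limitations

- The physical model is deliberately crude: constant velocity, constant
  (default zero) air resistance, no drafting, no curvature — the physics
  is a vehicle for texture description, not a cycling simulation.
- Features scale with `course_length`, `m` and `v`; comparisons across
  images are only meaningful at fixed parameters (the provenance sidecar
  written next to every feature CSV records them).
- Whole-image statistics: the descriptor does not localize roughness.
- The synthetic benchmark is far easier than clinical data; its accuracy
  says nothing about clinical performance.
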