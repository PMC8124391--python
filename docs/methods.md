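# Methods

This note records the models, estimators, parameter choices and known
limitations behind `conjuflow`, in the order the pipeline runs.

## Optical geometry

Object-space sampling is `pixel_pitch / magnification` µm/px; the defaults
(3.45 µm pitch, 3.798×) give 0.90837 µm/px, a 2.00 mm × 1.68 mm field of
view on the 2208×1848 px binned sensor region, and 8.26 px across a nominal
7.5 µm red blood cell — comfortably above the 4–5 px/RBC needed for reliable
velocimetry. The magnification is taken as a single scalar input; the lens
train behind it is not modeled.

Conventions used everywhere: arrays are indexed `(row=y, col=x)`,
displacements are `(dx, dy)` with +x rightward and +y downward, intensities
are float in [0, 1] (integer input rescaled by dtype maximum), RGB reduces
to the green channel at read time.

## Frame quality and coarse registration

The contrast index is the mean Sobel gradient magnitude of the frame. The
intensity surface itself carries no contrast information in its mean, so the
index is computed on the edge image; it is invariant to additive offsets and
linear in multiplicative gain. Frames with index below 95% of the sequence
maximum are rejected (inclusive comparison, so the best frame always
survives); ties for the template resolve to the earliest frame, for
determinism.

Registration is integer-pixel and translation-only: over a ~3 s recording,
ocular motion at this field of view is dominated by translation, and the
downstream template-matching step refines whatever remains. A central crop
of the template (margins = `search_radius`, default 64 px) is located in
each frame by zero-mean normalized cross-correlation; the zero-mean variant
is used here because whole-frame matching must tolerate smooth illumination
differences. Vacated borders after shifting are filled with the frame
median, a neutral value for later correlation. Sub-pixel registration is
deliberately absent: residuals below 1 px (≈0.9 µm) are at the scale the
second correction step reports.

## Segmentation

Full images are prepared by green-channel extraction, 0.5× downscaling and
CLAHE (8×8 tiles; the clip limit is expressed in the familiar
histogram-count convention, default 2.0, and converted to the normalized
limit of scikit-image internally). Training samples are random square crops
with side uniform in 64–128 px, resized to 64×64 (labels nearest-neighbor,
re-binarized), optionally augmented — rotation ±30°, shear ±0.2,
translation ±8 px applied to patch and label alike, and linear motion blur
of 3–9 px applied to the intensity only — each with probability 0.5, then
normalized per patch to zero mean and unit variance (constant patches
become zeros).

The network is a three-stage attention U-Net: per encoder stage two 3×3
stride-1 convolutions each followed by batch normalization and ReLU, then
2×2 max pooling; filter counts double per stage from `base_filters`
(default 32); a bottom stage without pooling; per decoder stage a
transposed 3×3 stride-2 convolution, an additive attention gate on the skip
connection (1×1 projections of skip and gating signals, ReLU, 1×1 + sigmoid
coefficient map multiplied onto the skip features), concatenation, and two
conv-BN-ReLU blocks; a 1×1 convolution and per-pixel softmax over
{background, vessel} close the model. It is implemented directly in numpy
(im2col + BLAS matmul, hand-written backward passes, float32), which keeps
small models practical to train on one CPU core and every result exactly
reproducible from a single seed. The loss is one minus the soft Dice
coefficient with an ε = 1e−6 guard in numerator and denominator against
empty masks. Training uses Adam; the default protocol is 150 epochs at
lr 5e−5 with reduce-on-plateau (×0.1 after 15 stalled epochs) and a 4:1
train/validation split, with best-on-validation weights restored.

The *scaled-down experiment* exercised by the tests trains on 2,000
synthetic patches for 20 epochs with `base_filters=4`, lr 1e−3 and batch 32
— the natural rescaling of the full protocol to a small, easy synthetic
problem — and evaluates on a full held-out scene never seen during
training. Inference on full images averages the first 30 registered frames
(temporal averaging reveals faint vessels), tiles with 64×64 windows at 50%
overlap, normalizes each tile exactly as in training, and blends
probabilities across overlaps before thresholding at 0.5; blending avoids
seam artifacts at tile borders. A multiscale Hessian vesselness baseline
(Frangi filter, Otsu threshold, small-object removal) is provided so the
pipeline runs without any training.

## Morphometry

Skeletons come from iterative thinning. The junction rule counts skeleton
pixels among the 8 neighbors of each skeleton pixel, center excluded — with
the center included a three-armed bifurcation would count 4, contradicting
the 3 = bifurcation / >3 = crossover classification. Removing junction
pixels separates the skeleton into segments; components shorter than 20 px
are discarded as not being part of a connected vascular network. Segment
length is the raw pixel count by default (a √2-weighted diagonal option
exists). Diameter per centerline pixel is `2d − 1` where `d` is the
Euclidean distance-transform value: `d` measures center-to-center distance
to the nearest background pixel, and `2d − 1` is exact for odd discrete
widths; the median across the segment's pixels is robust to
junction-adjacent inflation. On drawn ribbons of odd widths 3–15 px the
estimator is exact.

## Fine stabilization

The template vessel maximizes `w₁·L̂ + w₂·D̂` over segments with length and
diameter min–max normalized (weights default to 0.5/0.5; single-segment
graphs score 1). The template image is the segment's bounding box padded by
half its diameter plus a 5 px margin, cropped from the registration
template frame. Matching uses the plain normalized correlation coefficient
(no mean subtraction) as the default, with a zero-mean variant behind a
flag for scenes with strong illumination drift; scoring is exact
(sliding-window einsum) for small problems and switches to an FFT
formulation, equivalent to ~1e−12, for large ones. Ties at the correlation
peak resolve to the smallest displacement magnitude, then row-major order.
Frames whose peak correlation falls below 0.5 are flagged and excluded from
velocimetry rather than interpolated. Matching is integer-pixel; a
sub-pixel parabolic refinement of the peak is available but off by default.

One caveat surfaced by the synthetic experiments: because the template is
cropped from a single frame, the RBC pattern inside the vessel can drag the
match by 1–3 px *along* the vessel axis as clusters advance. Across the
default scenes this leaves the mean absolute residual under 1 px, but it is
the dominant error source of the second step.

## Velocimetry

The observability index is `α·σ̂t + β·L̂` with α = β = 0.5 and min–max
normalization across segments — the same normalization the template score
uses, applied here because variance (intensity²) and length (pixels) are
not commensurable; σt is the temporal variance of each centerline pixel's
intensity averaged along the segment. The top 15 segments are analyzed.

The STA image stacks each frame's centerline intensity profile as one
column, ordered from the chain endpoint with the smaller (row, col).
Columns carry their frame's true acquisition index, so sequences with
rejected frames keep real timing and the slope-to-velocity conversion uses
true Δt. The row scale is the segment's *smoothed* Euclidean arc length
divided by (n−1) pixels, in µm: a raw 8-connected chain advances √2 px per
diagonal step and, being slightly jagged, overstates its own arc length by
several percent; a 5-point moving-average of the coordinates before summing
step lengths removes both biases (a plain µm/px row scale underestimates
speed by cos θ on oblique vessels, up to 29%).

Slope extraction is automatic: the STA is detrended by subtracting each
row's temporal median (removing the static vessel and illumination), the
negative part is taken as streak amplitude, and a candidate slope deskews
the image by shifting column *t* down by `slope·t` rows with wraparound;
the true slope aligns all streaks horizontally and maximizes the variance
of the row-mean profile. Wraparound keeps every row fully sampled at every
candidate slope — without it, steep slopes are scored on few samples and
their variance is biased upward. The search runs on a geometric grid of
240 slopes in ±[0.15, 25] rows/frame, refines twice on shrinking local
grids, and finishes with a parabolic vertex step, resolving slopes near
15 rows/frame to ~1%. A detection is accepted only if the peak variance
exceeds 3× the median over the grid (pure noise scores uniformly, so no
streak is reported rather than a zero velocity); individual streaks are
peaks of the aligned profile with prominence ≥ 0.3 of its range. Velocity
is the mean over detected streaks of `|slope|·row_scale·fps/1000` mm/s;
sign (flow direction) is discarded.

## Synthetic scenes

The generator emulates what the measurement chain must survive, not the
tissue's appearance: dark smooth-curved vessels (cubic splines between
jittered border anchors) of 8–16 µm diameter on a bright background with
smooth uneven illumination; RBC clusters as Gaussian-profile dark blobs
spaced ~70 px apart advancing along each centerline at a constant
configured speed (0.05–0.4 mm/s, wrapping at the ends); global motion as
integer-pixel sinusoidal drift (amplitude 5 px, period 2.8 s) plus
persistent saccadic jumps (defaults: +18,−12 at frame 23 and −22,+15 at
frame 47); linear motion blur of 18 px on designated frames — comparable to
the saccade amplitude, as blur during a rapid transition should be — and
additive Gaussian noise with σ = vessel_contrast / SNR (default SNR 10).
Everything renders on a canvas padded 64 px beyond the frame so shifts
reveal real content, and one seed fixes all randomness, making scenes
byte-reproducible.

What the generator does *not* emulate: sclera texture, pulsatile (cardiac)
velocity modulation, vessel-diameter variation along a segment, specular
reflections, and sub-pixel global motion (available behind a flag but off
by default so registration recovery can be exact). Passing the synthetic
suite therefore demonstrates the estimators recover known kinematics under
noise, motion and blur — not segmentation performance on real tissue, which
depends on training data this package does not ship.

## Scale of the shipped experiments

The test suite and the acceptance script run everything at sizes chosen for
a single CPU core: 320×448 px, 70-frame scenes; the 2,000-patch / 20-epoch
training experiment with a `base_filters=4` network (~34k parameters); the
brute-force correlation oracle on 32×32/8×8 instances. The full-scale
protocol (300,000 patches, 240,000/60,000 split, 150 epochs, base_filters
32) is expressed in the defaults of `TrainConfig` and `UNetSpec` and is
exercised arithmetically, not executed.

## Known limitations

* Integer-pixel correction floors the achievable residual at ~0.45 px RMS;
  consistent with the ~1 µm regime reported for this class of system.
* The slope search assumes one dominant streak orientation per vessel;
  bidirectional flow in a single segment would be reported as the stronger
  direction only.
* Junction classification by neighbor count mislabels pixels adjacent to a
  true junction on thick-adjacency skeletons (a T-stem neighbor can read 4);
  junction *removal* is unaffected, so segment separation is correct.
* The attention U-Net here is a faithful but small re-implementation;
  nothing in the package reproduces training on real conjunctiva/fundus
  data, and no pretrained weights are shipped.
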