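# Methods

`icgfa` implements a perfusion-interpretation pipeline for indocyanine
green fluorescence angiography (ICGFA) of bowel: from a paired
white-light/near-infrared (NIR) recording of a segment intended for
transection, it predicts per-location perfusion classes along a sampled
line — `good` (well-perfused), `expert` (the band an experienced surgeon
would staple across) and `poor` (non-perfused) — and extracts the
recommended stapling zone. Because no surgical recordings are distributed
with the package, a synthetic scene generator with known ground truth
drives all training, testing and the headline experiment.

## Synthetic scenes

A scene is a horizontal bowel band across a 360×480-pixel field, recorded
for 90 s after dye injection. Each pixel's NIR intensity follows a
gamma-variate bolus curve

    I(t) = baseline                                           t ≤ t0
    I(t) = baseline + A·((t−t0)/tp)^α · exp(α·(1−(t−t0)/tp))  t > t0

the standard parametric model of first-pass dye passage; it peaks at
exactly `baseline + A` at `t = t0 + tp`, which gives closed-form oracles
for the milestone tests. Kinetic parameters vary along the bowel: constant
"good" values (high amplitude, early arrival) up to the proximal edge of
the expert band, a piecewise-linear interpolation good → expert → poor
across the 12-module band, and "poor" values (weak, late) beyond the
fluorescence boundary. The label runs therefore coincide with the
parameter-interpolation breakpoints by construction. Default parameter
ranges (amplitude 150–180 / 70–110 / 4–14 intensity units, arrival 10–14 /
14–18 / 26–34 s, rise time 13–18 / 19–25 / 30–40 s for good/expert/poor,
shape 1.8–2.5, baseline 5–10) were chosen once as a plausible first-pass
contrast between perfused and non-perfused bowel on an 8-bit sensor; they
are configuration, not clinical claims. A scene distribution additionally
draws the boundary position from the central 40–70% of the field.
Mal-perfused scenes (`perfusion="poor"`) use poor kinetics everywhere and
carry no expert band and no stapler annotation.

The white-light channel is a static, seeded multi-scale blob texture; its
hue is constrained to G = max(R, B) per pixel so that the green-overlay
display rendering (tissue attenuated by `1 − f/255`, green channel plus
`f`) is exactly inverted by the green-excess extraction formula — the
overlay/native round-trip is then testable to quantisation (≤ 1 unit).
Camera jitter is a per-frame affine (translation, small rotation and
shear, all scaled by `motion_amplitude` in pixels, frame 0 = identity);
Gaussian sensor noise is added after warping. All randomness flows from
one scene seed, so a fixed seed reproduces a scene bit-for-bit.

The default frame rate is 2 Hz. Clinical imagers record faster, but the
inflow milestones live on a seconds time-scale; 2 Hz samples the 30-s
analysis window with 60 frames and keeps whole-corpus experiments
desk-sized. What the generator does **not** model: ICG recirculation and
second-pass kinetics, diffusion spread across the boundary over time,
specular highlights, occlusions, instruments in the field, and
non-affine (peristaltic) tissue deformation. Green tests on this corpus
therefore demonstrate correctness of the pipeline's mechanics and its
behaviour under the stated noise/motion model — not clinical performance.

## Stabilisation

Every frame is registered to the first frame with an affine transform
estimated on the white-light channel (the NIR channel is dark before dye
arrival) and the identical warp is applied to the synchronous NIR frame.
The estimator detects Shi-Tomasi corners on the reference frame, matches
16×16 intensity patches into the moving frame by SSD over a bounded search
window (FFT-accelerated, with a second-minimum ratio test and parabolic
sub-pixel refinement), and fits the affine by random-sample consensus
(residual threshold 2 px). On synthetic motion this recovers translations
and 3° rotations to well under 0.5 px/0.5°. Per-frame failures fall back
to the previous frame's transform (identity for the first), on the
grounds of temporal continuity of camera motion; warping is bilinear with
zero fill, and a per-pixel validity mask excludes warped-in border pixels
from all downstream means.

## Grid extraction and curve milestones

Stabilised frames are segmented into a 72×96 grid of 5×5-pixel modules;
each module's value is the arithmetic mean of its valid pixels (mean
rather than median for linearity). Overlay-display recordings are first
reduced to a fluorescence estimate `clamp(G − max(R,B), 0, 255)`, which
nulls achromatic tissue exactly; the alternative `G − (R+B)/2` leaves
residue on warm-toned tissue and is rejected (the choice is exposed in
configuration). Frames of other sizes are resampled to 360×480.

Each cell's curve over the analysis window is summarised by four
milestones. The window starts at the recording's global inflow onset (the
first frame where the spatial mean exceeds its early baseline by 3
baseline standard deviations, with a 0.5-unit floor for noiseless input)
and spans 30 s. The curve is smoothed by a centred 3-frame moving average
(minimal noise rejection without biasing the peak at 2 Hz); the baseline
is the mean of the first three smoothed samples (recording starts at
injection, so early frames are pre-inflow). Then

* `i_max` — maximum of the smoothed curve; `t_max` — time of its first
  attainment;
* `t_half` — first upward crossing of baseline + 0.5·rise, linearly
  interpolated between samples and constrained to [t_onset, t_max];
* `upslope` — rise/(t_max − t_onset) with `t_onset` the 10%-rise
  crossing, a standard "slope of inflow" definition; a max-derivative
  variant is available in configuration for sensitivity analysis.

Flat curves (rise ≤ 1e−9) are flagged degenerate with all-zero features.
Cells valid in under half of the window frames are flagged invalid.

Features are normalised per recording: `i_max` and `upslope` min–max to
[0, 1], times divided by the window length. The min–max denominator is
floored (32 intensity units, 2 units/s) so a recording with no real
inflow — mal-perfused bowel whose dynamic range is just noise — is
compressed towards zero rather than noise-stretched to full scale; this
is what lets the sequence model decline to predict a zone on such scenes.
The scaling actually applied is stored and exactly invertible.
Per-recording scaling removes device gain and illumination differences
between recordings.

## Lines, condensation, labels

Prediction operates on lines crossing the fluorescent/non-fluorescent
boundary, proximal → distal (canonical orientation; the sequence model is
direction-sensitive). At each line coordinate (one per grid module of arc
length) a 35-pixel-high rectangle perpendicular to the line collects 7
cells; each milestone is condensed to one value per coordinate by the
median across those cells (features are medianed, not raw intensities;
the alternative ordering is available in configuration). Coordinates with
no valid cell are filled by linear interpolation along the line.
Coordinates inside the 12-module stapler band are labelled `expert`,
proximal ones `good`, distal ones `poor`.

Augmentation samples 4 lines per segment with endpoint trims up to ±20%
of the base length (drawn within the range that keeps the stapler band
plus margin inside the line) and perpendicular offsets up to ±10 modules,
seeded. With several annotating experts, each expert's stapling site
yields its own labelled copies of the same 4 line geometries, so a corpus
of V videos gives exactly V×4×E samples. Simulated experts shift the
band centre by up to ±2 modules, never distal of the boundary.

## Classifiers

**Point model.** Inverse-distance-weighted K-nearest neighbours (default
k = 10) on the 4 normalised features, Euclidean metric. Ties are broken
by smaller mean neighbour distance, then by the fixed class order
good < expert < poor; an exact feature match wins outright. Training
reports 10-fold cross-validated accuracy with folds grouped by line
sample (points of one line never straddle folds, avoiding leakage between
neighbouring coordinates).

**Sequence model.** A five-layer network — sequence input, bidirectional
LSTM with 200 hidden units per direction, fully connected, soft-max,
classification output — implemented directly in numpy (forward pass,
backpropagation through time, Adam). Training uses learning rate 1e−3,
batches of 8 variable-length sequences padded with loss masking, at most
60 epochs, and early stopping on validation loss with patience 5; the
weights of the best validation epoch are kept. Class weights are inverse
frequencies (≈12 expert modules versus ~80 others per line). Correctness
of the hand-written gradients is pinned by a finite-difference check in
the test suite; fixed seeds make initialisation, batching and hence the
trained weights reproducible. The single-expert and three-expert variants
share this architecture and training routine, differing only in corpus.

## Zone extraction and evaluation

The predicted expert zone is the longest contiguous run of expert labels
of length ≥ 6 modules (half a stapler diameter — a shorter run is noise,
not a transection recommendation; configurable), ties resolved towards
the proximal end; with no qualifying run the prediction is an explicit
no-prediction and the overlay shows only non-expert zoning. Pixel-level
metrics binarise expert-vs-rest and pool confusion counts over all test
coordinates (micro-average); DICE = 2|P∩G|/(|P|+|G|) equals F1 in this
set formulation and both are reported. When predicted and true expert
sets are both empty the overlap metrics are reported as 1 with a
`vacuous` flag — this correctly rewards no-prediction on truly
mal-perfused segments. Object-level accuracy asks whether the stapler
band **centre** lies inside the half-open predicted zone (a 12-module
band may legitimately overhang a correct narrow zone; an any-overlap rule
is available). Segments without a stapler band are excluded from the
object denominator.

## Problem sizes and numerical choices

The headline experiment (also run by `scripts/acceptance.py`) trains the
sequence model on 20 scenes (80 augmented lines) with 5 validation scenes
and tests on 15 held-out scenes including 3 mal-perfused ones — the
corpus sizes of the single-expert protocol. The unit-test suite runs the
same pipeline mostly on a reduced geometry (24×32 grid over 120×160
pixels, 45 s) that exercises identical code paths at a fraction of the
cost. Tolerances used by tests derive from the constructions themselves:
uint8 quantisation (0.5), overlay round-trip (1 unit), dense-scan oracle
resolution (milliseconds), registration (0.5 px / 0.5°, mean series error
≤ 2 units against a motion-free twin). Degenerate inputs (flat curves,
blank frames, empty splits, all-invalid cells) raise typed errors or
flags rather than propagating NaNs.

## Known limitations

* The synthetic corpus is far cleaner than surgical video; reported
  synthetic metrics are upper bounds of mechanism, not clinical claims.
* Registration assumes rigid-ish affine motion; peristalsis and
  instrument occlusion are out of scope.
* Line placement is annotation-driven; the package does not detect the
  perfusion boundary automatically.
* The KNN model classifies points independently and, as expected, tends
  not to produce a clean contiguous stapling zone; it is retained as the
  comparison baseline.
* Statistical comparison between the one-expert and three-expert sequence
  variants, and inter-rater agreement between simulated experts, are not
  implemented.
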