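# Methods

## The problem

An isolated larval *Drosophila* central nervous system generates fictive
motor programs that mirror crawling: forward waves (FW) of segmental
activity propagating posterior→anterior, backward waves (BW) propagating
anterior→posterior, left/right-asymmetric anterior bursts (AT, turn-related),
synchronous posterior bursts (PT), and quiescence (QS).  Given calcium-imaging
fluorescence from 18 hemisegmental ROIs (neuromeres T2–A7, both sides), the
package segments the recording into these states and locates, voxel by voxel,
the cells whose activity follows each state.

## Preprocessing

For each ROI the baseline at frame *t* is the mean raw fluorescence of the
preceding 16 frames, and

ΔF/F(t) = max(0, F(t) / F_base(t) − 1).

Rectification reflects that the indicator (GCaMP6f) reports activity while
its signal rises, and the short running baseline absorbs slow photobleaching.
The first 16 frames have no baseline and are dropped (2048 frames → 2032
valid frames).  For bright motoneuron drivers, ΔF/F is capped at 2
(`clip_value`; disable for dim reporters).  The matrix is then min–max scaled
to [0, 1] **globally** (not per ROI) so inter-segment intensity ratios
survive — the burst/wave discrimination rules depend on them.  A constant
matrix scales to zeros.  Finally the 18 hemisegmental traces are compressed
to 9 segmental traces by the left/right maximum, so activity on either side
is retained; the 18-ROI traces are kept for the asymmetry statistics.

## Windows and images

The 9-ROI series is cut into 8-frame windows (window centered at *t* covers
*t*−4 … *t*+3; centers run 4 … T−5, so T frames give T−8 windows; 2032 →
2024).  Each 9×8 window is encoded as a 72×72×3 8-bit image: values map by
`floor(v·255)`, the time axis (rows) is replicated ×9 and the ROI axis
(columns) ×8 — exact integer nearest-neighbour replication, no
interpolation — and the grayscale plane is copied to all three channels.
Rows are time and columns are ROIs (anterior left); any fixed orientation
works for clustering, this one is asserted by the tests.

## Features

Window images pass through the VGG-16 convolutional stack to Conv4_3 (the
third convolution of block 4).  On 72×72 input the three preceding 2×2
poolings leave a 512-channel 9×9 map; global average pooling over the 81
positions gives one 512-vector per window.  The forward pass is implemented
directly in numpy (3×3 same-padding convolutions as nine shifted GEMMs,
ReLU, max-pooling), in float32, with results independent of batch size.

Backbones:

* `vgg16-random` (default): seed-deterministic He-initialized weights.  A
  random deep convolutional network is a fixed nonlinear projection that
  preserves image similarity; unsupervised clustering downstream only needs
  a geometry in which similar windows are close, so no training or download
  is required and every run is bit-reproducible.
* `vgg16-pretrained`: same architecture, weights from a user-supplied `.npz`
  (arrays `conv{i}_w` shaped (3, 3, Cin, Cout) and `conv{i}_b`); raises a
  clear error when no file is given.
* `blockmean`: 8×8 block means of the raw image (81-dim); a degraded
  fallback useful for fast smoke tests, not feature-equivalent.

Before the forward pass, images are normalized with the canonical ImageNet
channel statistics; a `raw` mode feeds unscaled 0–255 values (both modes are
exercised by the tests; the choice does not change the pipeline's behaviour
class on synthetic data).  The tap layer is configurable; Conv4_3 is the
default.

## Clustering and labeling

Features are clustered by Ward's-method agglomerative clustering (Euclidean
distance — required by Ward) and the tree is cut at a fixed
`n_clusters = 25`.

Labeling maps clusters to motor patterns.  The rule set, applied in order to
a window (or mean window):

1. mean intensity < `theta_qs` (0.05) → QS;
2. |slope| of the intensity centre of mass (in segment index, regressed on
   the frame index) > `theta_wave` (0.25 segments/frame) → FW if the drift
   is anterior-ward (negative), else BW;
3. anterior-zone (T2–A4) intensity fraction > `theta_at` (0.7) → AT;
   posterior-zone (A4–A7) fraction > `theta_pt` (0.7) → PT (A4 belongs to
   both zones; if both rules fire the heavier zone wins);
4. otherwise UL.

Wave rules precede burst rules because propagation is the more specific
signature.

Two measured facts shaped the final labeling design.  First, windows that
straddle an event boundary mix two patterns, and the rules then misread
them (e.g. an anterior-burst window carrying the decaying tail of a
backward wave acquires a spurious centre-of-mass drift).  The classifier
therefore grows a *coherent sub-window* from the centre column outward,
extending while adjacent columns stay similar (cosine similarity >
`theta_cos` = 0.5 and column norm > `theta_gap` = 0.1), and applies the
rules to that sub-window — the label belongs to whatever pattern occupies
the window's centre frame.  Second, cluster mean images blur the many
phases a cluster contains, so clusters are labeled by a *purity-gated
majority vote*: every window is classified individually; when at least
`vote_purity` = 80 % of a cluster's members agree, the majority label
overrides the members (the cluster acts as a denoiser), otherwise the
cluster is treated as mixed and its windows keep their own labels.  Manual
overrides (`cluster=LABEL`) force a label onto a whole cluster and take
precedence, preserving the human-in-the-loop escape hatch of the original
visual procedure.  `auto_label_clusters` still labels plain mean windows
for diagnostic use.

All labeling thresholds were calibrated once on the synthetic generator and
live in `RunConfig`.

## From labels to events

Frame *t* takes the label of the window centered at *t*; the 4 frames at
each edge, which no centre covers, copy the nearest window's label (2024
window labels → 2032 frame labels).  Window-level labels flicker near event
boundaries, producing 1–2-frame fragments far shorter than any real motor
pattern (the shortest class dwell averages 1.5 s ≈ 8 frames); runs shorter
than `min_event_s` = 0.9 s are therefore absorbed into the longer adjacent
run before run-length encoding.  Maximal same-label runs become events
(QS and UL runs included; UL is dropped only where a statistic excludes it).

Evaluation against ground truth is event-level: a truth event is a **hit**
when a predicted event of the same class overlaps ≥ `overlap_threshold`
(0.5) of its span; a predicted event is a **false alarm** when it overlaps
no truth event of its class.  A class with no truth events reports an
undefined (missing) hit rate rather than 0.

## Statistics

Per class: events/minute; intensity (max ΔF_norm over all ROIs and frames
of the event); the asymmetry index |max_L − max_R| / max_all per frame
(undefined when all ROIs are 0); event-level Markov transition matrices
over a chosen state set (UL always removed first — removal concatenates
neighbours, which is what creates same-state transitions such as QS→QS);
and end-aligned average activity profiles (segments anchored at event end,
default 4 s before to 1 s after, truncated segments excluded) with mean ±
sd durations.  Transition rows with no outgoing events are flagged
undefined, not zero.

## Correlation mapping

Voxel-wise ΔF/F uses the same rectified running-baseline formula.  The
**behavior map** for a pattern is the Pearson r between each voxel's ΔF/F
and the 0/1 indicator of that pattern over the valid frames (the indicator
and the voxel series share the same origin: both drop the first 16 frames).
Exactly-constant voxels and constant indicators give missing values, never
silent zeros.  The **dominant map** assigns each voxel the pattern of its
largest r where that r exceeds 0.1 (ties break by the fixed order AT, BW,
FW, PT).  The **ROI map** correlates voxels with the ΔF/F of a seed
region's summed fluorescence and refines the region to the voxels with
r ≥ 0.05 in a single pass (an optional iteration count repeats
refine→re-correlate for exploration).  Input movies are assumed registered.

## Synthetic generator

The generator is the package's test bed and defines its study conditions:

* **State process**: semi-Markov chain over {AT, BW, FW, PT, QS} with a
  biased transition matrix (BW→AT and FW→PT strongest at 0.6, AT→BW and
  PT→FW 0.6, AT↔PT 0.2, no direct FW↔BW, zero diagonal) and lognormal
  dwell times with class means 2.2/2.8/2.3/1.5/2.9 s (sd ≈ 25–40 %),
  matching the durations seen in isolated nerve cords.
* **Templates**: waves are Gaussian bumps (σ = 0.9 segments) traversing the
  full segment axis over the event duration (FW posterior→anterior, BW the
  reverse); AT is a plateau over T2–A4 with one side's amplitude scaled by
  a factor drawn from U(0.1, 0.5) (random side per event); PT is a
  symmetric plateau over A4–A7; QS adds nothing.  Event envelopes have a
  1-frame half-cosine ramp.
* **Measurement model**: baseline fluorescence 100 a.u., exponential
  photobleaching (τ = 600 s), peak event ΔF/F 1.0, additive Gaussian noise
  with sd 2 % of baseline, 180 ms frame interval (the fastest imaging
  condition), values floored just above zero.
* **Movies**: a (z=2, y=32, x=64) lattice with 18 disk-shaped hemisegmental
  units carrying the ROI traces, plus one planted midline unit active
  *only* during BW — the stand-in for a backward-specific interneuron that
  behavior mapping must recover — and background noise.

What the generator does **not** emulate: GCaMP kinetics (rise/decay
convolution), motion artefacts, optics/PSF blur, neuropil contamination,
amplitude drift across events, or overlapping motor patterns.  Passing
tests therefore demonstrate the pipeline's correctness and its behaviour
under the stated statistical structure, not performance on real
recordings.

## Problem sizes and numerical choices

The acceptance checks run the full pipeline at the study scale of one
recording (18 ROIs × 2048 frames → 2024 windows); transition recovery uses
a ≈ 1800-event sequence; correlation mapping uses a 600-frame movie
(≈ 4000 voxels); determinism re-runs a 384-frame recording twice.  All
randomness flows through explicit `numpy.random.default_rng` seeds; there
is no global random state.  Ward linkage runs on float64 features; the CNN
forward pass is float32.  Degenerate cases are pinned by tests: constant
ΔF/F matrices normalize to zeros, empty clusters warn and are excluded,
zero-variance voxels give missing correlations, transition rows without
events are flagged undefined, and an all-QS series yields a single event.

## Known limitations

Random-weight features are weaker than ImageNet-pretrained ones; the
purity-gated voting compensates on synthetic data, but on real recordings
the pretrained backbone (user-supplied weights) should be preferred.  The
auto-labeling rules assume the anterior/posterior zone layout of T2–A7
recordings and 8-frame windows at ≈ 0.2 s/frame; other window sizes work
mechanically but the calibrated thresholds may not transfer.  Hit/false-alarm
scoring is event-level; frame-level confusion is available only through the
per-frame series.
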