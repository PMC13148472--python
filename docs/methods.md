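# Methods

## Model and pipeline

`arenatrack` tracks one animal per region of interest (ROI). The operating
assumption — one fish per well, one fish per maze — removes the
data-association problem entirely: each ROI owns exactly one track, and an
identity swap is impossible by construction. All stages are deterministic
functions of the input frames and the run configuration.

### Background: per-pixel mode

The background is the per-pixel mode of the 8-bit intensity histogram over
sampled frames (`sample_stride` default 10). A pixel occupied by the animal
in fewer than half of the samples can never win the vote, so a sufficiently
mobile animal is excluded exactly and the estimate equals the empty arena
bit-for-bit — this exclusion property is tested literally. Ties break
toward the smallest tied intensity, making the estimate deterministic. The
per-pixel histograms (256 bins, h·w·256 counters) are retained on the
`BackgroundImage`, so streaming operation can bootstrap a background from
the first ~300 frames and fold new samples in later (`refresh_background`)
without revisiting old frames.

The stride trades compute for vote count: with stride 10, a movie shorter
than a few hundred frames leaves too few samples for reliable exclusion.
The pipeline defaults assume recordings of at least ~200 frames; short
clips should lower `background_stride` (the short-fixture tests use 2).

### Segmentation: incremental SSIM

Each frame is compared to the background with the structural similarity
index over a uniform 7×7 window (`win_size=7`, K₁=0.01, K₂=0.03, L=255 —
the standard constants for 8-bit images; all exposed in `RunConfig`).
Window means use reflective padding so the difference image keeps full
frame shape. Because the background is fixed, its windowed statistics are
computed once (`build_context`); per frame only µₓ, µₓₓ and µₓ_y are
needed. The equivalence of this incremental form with full recomputation
(and with scikit-image's SSIM under a uniform window and population
covariance) is asserted to 1e-10 — the caching is an optimization, not an
approximation.

Dissimilarity D = clip((1−S)/2, 0, 1) maps identical regions to 0 and
maximal dissimilarity to 1. The mask D ≥ `threshold` (default 0.35) is
decomposed into connected components within each ROI independently;
components with area in [`min_area`, `max_area`] (defaults 4 px² and 1/4 of
the ROI area — a plausibility gate against specks and global lighting
changes) are candidates, and the largest passer becomes the ROI's single
detection, with an intensity-weighted centroid on D. The area gate is a
design choice: nothing in the SSIM map itself distinguishes an animal from
other change, so plausible-size is the confidence criterion.

### Tracking: constant-velocity Kalman filter

State (x, y, vx, vy), Δt = 1 frame, piecewise-constant white-acceleration
process noise q = 0.01 px²/frame⁴ and measurement noise r = 1.0 px²
(defaults chosen for slow, smooth larval swimming at 30 fps; both exposed).
The filter initializes at the first detection with zero velocity. Missing
detections are coasted (predict-only) for up to `max_coast` = 15 frames
(0.5 s at 30 fps), after which the track holds position; coasted and held
frames are flagged invalid and excluded from displacement metrics. Tracks
in which no two positions within a 30-frame window ever differ by more than
1.5 px are pruned as static debris. The lag-based formulation used for
pruning (any pair at lag < window) is exactly the max-pairwise-displacement
criterion, vectorized.

### Larval metrics

dpix — pixels changing by strictly more than `dpix_threshold` = 10
intensity levels between consecutive frames inside the ROI — is the
activity currency. A second is *active* when its summed dpix exceeds 3;
bouts start when dpix > 2 and end after 5 consecutive quiet frames; these
are calibration knobs with no canonical values, all config-exposed. Bout
displacement is start-to-end straight-line distance; stimulus response
displacement is the *path length* of the smoothed trajectory during the
stimulus (a darting response that returns home should not score zero).
Stimulus alignment requires the full ±`window_s` context inside the track
span; partially covered events are skipped and counted, keeping all traces
equal-length and alignable.

### Y-maze analysis

Arms are labeled 0, 1, 2 counterclockwise; transition a → (a+1) mod 3 is a
left turn, a → (a+2) mod 3 a right turn. The convention is arbitrary: the
mirror-symmetry property (letter-swapping under reflection, invariant
alternation statistics) is tested, so no headline number depends on it.
An arm entry requires `debounce_frames` = 5 consecutive frames (~167 ms at
30 fps) inside the arm polygon, suppressing boundary jitter; center-zone
dwell does not end an arm occupancy, and arm → center → same arm excursions
produce no turn.

Tetragrams are overlapping stride-1 windows of four turns, timestamped by
their fourth turn, which also assigns them to 10-minute bins of the 1-hour
session. Alternation percentage = 100·(LRLR+RLRL)/total; under fair
independent turns each of the 16 words has probability 1/16, so chance is
2/16 = 12.5%. Equivalently, the 16 words collapse into 8 mirror-pair
classes of probability 1/8 each, with the alternation class {LRLR, RLRL}
one of them; the package reports both the 16 raw counts and the 8 classes.
Per-bin alternation percentages are tested against 12.5% with one-sample
t-tests, Benjamini–Hochberg-adjusted across bins; zero-variance bins are
flagged degenerate rather than silently dropped. In live assays the fish
habituates behind a comb before release; analysis expects track time zero
at release, and a recording that includes the habituation period should be
trimmed before analysis (`session_s` covers the 1-h exploration only).

### Agreement statistics

Pearson r, paired and one-sample t, and Kruskal–Wallis wrap scipy with
input validation and explicit degenerate-case behavior (all-zero paired
differences → t = 0, p = 1; constant nonzero differences → ±inf, p
missing). The single-rater ICCs are authored from the two-way ANOVA mean
squares: ICC(2,1) = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n) (absolute
agreement, two-way random) and ICC(3,1) = (MSR−MSE)/(MSR+(k−1)MSE)
(consistency, two-way mixed), with p from F = MSR/MSE on (n−1, (n−1)(k−1))
df. They are verified against brute-force sums-of-squares oracles and
against pingouin in the test suite; pingouin is a test-only dependency.

## Synthetic scenes: what they emulate and what they do not

The renderer emulates IR-backlit arenas: uniform background (default
intensity 200), one dark Gaussian-profile blob per ROI (profile scale =
radius/2, default radius 3 px), i.i.d. Gaussian pixel noise (default σ = 2),
8-bit quantization. Contrast is |blob − background|/255, default 0.6.

* The 96-well preset swims each blob on a seeded Lissajous path (amplitude
  12 px, incommensurate x/y periods). The paths sweep most of the well so
  no pixel is occupied in a majority of frames — the premise of mode
  exclusion, which real roaming larvae satisfy; a genuinely torpid fish
  would contaminate the mode background in any implementation.
* The Y-maze preset converts a scripted turn string into a piecewise-linear
  path through arm waypoints (dwell 0.4 s per arm ≥ the debounce, travel
  through the maze center), constructed to be a right inverse of entry/turn
  extraction.

Deliberately absent: body shape and tail kinematics, motion blur,
illumination drift and flicker, reflections at well walls, fish occluding
arena landmarks, dropped frames. Passing the round-trip tests therefore
demonstrates correctness of the geometry, background, SSIM, filtering, and
turn-extraction machinery under the stated imaging model — not robustness
to every artifact of real video; the low-contrast scenes (contrast halved
to 0.3) probe sensitivity in the direction that matters most in practice.

## Problem sizes

The verification runs use scenes sized for a single CPU: 96 wells × 240
frames (340×500 px) for the plate round trip; 20 mazes × 30 scripted turns
(~850 frames at 600×480 px) for turn recovery at contrast 0.6 and 0.3;
20 × 100 turns for the geometric (vision-free) round trip; 10⁶ simulated
fair turns for the chance level; 100 random matrices and 10⁴ Gaussian-null
replicates for the statistics checks. Larger scenes change none of the
logic — rendering and SSIM cost scale linearly in pixels × frames.

## Known limitations

* One animal per ROI is structural; two animals in one well will be merged
  or the smaller one ignored (largest-component rule).
* The SSIM threshold (0.35) and area gates are tuned for blob-on-uniform
  scenes; textured backgrounds may need a higher threshold or a larger
  `min_area`.
* Kalman coasting assumes short gaps; an animal undetected for seconds
  reappears with a transient as the filter re-converges.
* H.264 containers are not decoded; supported inputs are TIFF stacks, .npy
  stacks, PNG frame directories, or in-memory arrays (the library surface
  takes plain numpy stacks).
* The t-tests treat per-fish alternation percentages as approximately
  normal; with very few tetragrams per bin the approximation is rough, and
  the Monte-Carlo null test bounds the resulting size distortion only under
  the simulated conditions.
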