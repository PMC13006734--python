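# Methods

This note documents the models, numerical choices, and open design
decisions behind `strainspeech`, and what the synthetic benchmarks do and
do not demonstrate.

## Optical strain sensing model

The sensor is modeled as a regular grid of dark circular markers on a light
substrate, imaged at 320 × 240 px with pixel centers at integer coordinates
(origin top-left, x right, y down). Surface deformation is modeled as a
plane projective transform H (3 × 3, H₂₂ = 1), optionally plus per-marker
local displacements. A homography is the exact image-to-image map for a
planar surface under camera projection and a good local approximation for
the gently curved throat surface at a 1–3 mm working distance; it is also
what the tracking stage fits, so the simulator and estimator share a model
family by construction.

Frames are rendered by 4× supersampled coverage of each circle, so circle
edges are anti-aliased and marker centroids remain recoverable to
sub-pixel accuracy (measured: ≲ 10⁻³ px RMSE on noiseless frames). Defaults
place a 5 × 6 marker grid at 24 px pitch with 6 px radius — about 30
markers in frame, comfortably more than the 16 markers of interest used for
tracking. The physical device's marker pitch in pixels is not prescribed
anywhere, so this is a package choice.

## Marker detection

Pipeline order: CLAHE → unsharp masking → Gaussian blur → 3 × 3 sharpening
convolution → border whitening → Otsu binarization → 8-connected component
extraction with an area filter ([20, 500] px² at the default radius).
Numerical choices:

* CLAHE clip limit 2.0 in the OpenCV convention, mapped to scikit-image's
  fractional clip as clip/100, with 8 × 8 tiles; Gaussian σ = 1.0. These are
  conventional values for small frames; a constant image is passed through
  unchanged since adaptive equalization of zero contrast is undefined.
* The sharpening kernel defaults to −1 in the 8-neighborhood with center
  +9 (the standard sharpening kernel); the center weight is configurable
  (e.g. 11) because both readings are defensible.
* Otsu's threshold is computed by an explicit exhaustive sweep over all 256
  thresholds maximizing between-class variance of the {≤ t}/{> t}
  partition, smallest argmax on ties. Owning the sweep fixes the tie-break
  and class conventions, which makes the partition exactly symmetric under
  intensity inversion; scikit-image's `threshold_otsu` serves as an
  independent cross-check in the tests. A constant image yields
  all-background with a logged warning.
* Centroids are darkness-weighted; components whose bounding box touches
  the whitened border (or frame edge) are dropped because a partially
  visible circle has a biased centroid — this matters once deformations
  push markers into the border, where centroid bias of up to ~0.8 px was
  measured before the filter was added.

With the default configuration, detection on noiseless synthetic frames has
100 % recall and centroid RMSE far below the 0.5 px contract.

## Strain mapping

The 16 markers of interest are the detections nearest the image center
((w−1)/2, (h−1)/2), ordered deterministically by (distance, x, y).
Cross-frame matching is purely positional (greedy one-to-one by ascending
distance): all markers are identical black dots, so appearance descriptors
carry no information. The default matching radius is pitch/2; inter-frame
displacements beyond that limit are not trackable without identity swaps,
which bounds the usable deformation rate of the simulated sensor.

The homography is estimated with RANSAC (ProjectiveTransform, residual
threshold 1.0 px, ≤ 1000 trials, seeded), then refit by least squares on
the inliers. Exact correspondences recover a ground-truth homography to
1 × 10⁻⁶ elementwise. Note that a homography fitted from markers covering
only part of the frame is reliable *interpolated* over that support but
degrades when extrapolated far outside it (the projective degrees of
freedom are weakly constrained); the fidelity benchmark therefore uses a
marker layout spanning the frame.

Strain maps are evaluated on a 12 × 16 lattice over the frame (the grid
size is a free parameter): amplitude(p) = ‖H·p − p‖₂ in px,
direction(p) = atan2(Δy, Δx) ∈ (−π, π] with y downward. A lattice point
mapped to infinity (vanishing homogeneous denominator) raises rather than
returning garbage.

The residual-deviation map pairs captured markers with the designed layout
after translating both to a common centroid, computed in centered
coordinates so the result is invariant to global translation of the
captured set up to floating-point roundoff (asserted at 10⁻⁸ in tests —
bitwise equality is not attainable for arbitrary real-valued shifts). The
relative-pixel-change metric ‖ΔMOI‖/‖MOI₀‖ measures coordinates from the
image center by default; a raw-origin convention is selectable but makes
the denominator depend on where the corner sits, which is why center is the
default.

## Signal conditioning and augmentation

Utterance sequences are T × C arrays at a nominal 50 Hz. The conditioning
chain is: window-5 centered moving average (shrinking windows at the
edges), validity check 100 ≤ T ≤ 220, symmetric zero-padding to 220 steps
(odd remainder trails, fixed for reproducibility), and z-scoring with
global training-corpus statistics (per-channel statistics optional; global
scalars are the default).

Training augmentation, applied to the padded sequence in order
warp → crop → scale: duplicate the values at 20 indices sampled *without*
replacement from [20, 200) (with replacement would allow triplication,
which "duplication" does not suggest), crop a uniformly placed 200-step
window, and scale by one α ~ U(0.9, 1.1) per call. Each augmentation is
deterministic given its generator.

Voice activity detection gates on the trailing 200-sample energy (sum of
squared channel norms — the energy formula itself is a package choice) and
then refines boundaries inside the gated span: the reported start/end are
the first/last samples whose instantaneous power exceeds
max(threshold, peak/2)/window. The refinement is needed because raw
trailing-window crossings lag the activity by up to one window, which would
let a 50-step burst masquerade as a valid 100–220-step segment. When no
threshold is given it is calibrated per stream as μ + 4σ of the energy over
the leading 400 samples.

## Word decoder

Architecture (teacher defaults): two strided 1-D conv blocks
(32 and 64 filters, kernel 5, stride 2; ReLU) reduce the 200-step input to
47 tokens of width 64; learned positional embeddings are added; two
post-norm transformer encoder layers (4 heads, feed-forward 128) reweight
the tokens; mean pooling gives a sequence embedding. The residual-map
branch (16 sorted per-marker deviations resampled to fixed length, matching
the MOI count) passes through a 32-unit ReLU layer and is concatenated at
the fully connected stage; a 64-unit hidden layer feeds the 26-way softmax.
≈ 90 k parameters, ~0.7 MB exported. The student halves every width
(≈ 16 k parameters). These sizes are deliberately desk-scale so that CPU
training is fast; all widths are configurable upward.

The network runs on an in-package reverse-mode autodiff engine over numpy
(float64, im2col convolutions, numerically shifted log-softmax), whose
gradients are verified against central finite differences for every layer.
Training uses Adam (lr 10⁻³ default), cross-entropy, batch 256 (evaluation
at batch 1), early stopping on validation loss with best-weight
checkpointing, and is bit-reproducible given the seed. A non-finite loss
aborts with a diagnostic rather than continuing.

Cross-validation uses a subject-independent stratified 5-fold plan:
subjects are assigned whole to folds (greedy size balancing after a seeded
shuffle), so no subject ever appears on both sides of a split; with classes
spread evenly over subjects each fold holds exactly 1/k of every class.

Distillation trains the student on
(1 − λ)·CE(hard) + λ·τ²·KL(teacher_τ ‖ student_τ) with τ = 4 and λ = 0.5
by default (values are package choices); λ = 0 reduces bit-exactly to
plain training. LoRA adaptation attaches rank-8 factors (α = 16, A
Gaussian, B zero — identity at initialization) to the query and value
projections of every encoder layer; only those factors (optionally plus the
head) receive gradients, about 4 % of parameters at default sizes, and the
frozen weights are asserted bit-identical afterwards.

Models export to a portable NPZ checkpoint: a JSON architecture record plus
every named parameter array (and, optionally, the training normalization
statistics so inference preprocesses identically). Reload reproduces
outputs exactly.

## DTW analytics

DTW uses the symmetric (↑, →, ↘) step pattern, boundary-matched, with
squared-Euclidean local cost across channels and no window constraint by
default (a Sakoe–Chiba band is optional). The dynamic program is verified
against exhaustive path enumeration on all small instances. Clustering is
k-medoids on the precomputed pairwise DTW matrix with farthest-point
initialization — exact, deterministic given the seed, and sufficient for
grouping attachment/intensity conditions; a barycenter-style center was
considered and rejected as unnecessary complexity for this use.

## Synthetic data: what it does and does not show

The generator emulates the study conditions end-to-end: 26 balanced word
classes built from smooth random per-class templates (shared across
subjects), subjects with per-channel gains (U(0.8, 1.2)) and speaking-speed
factors (U(0.85, 1.15)) that modulate utterance length, lengths confined to
the 100–220-step validity window, and a small number of attachment states.
Each state carries a smooth per-marker deviation field whose strength also
shifts the per-channel signal baseline, reproducing the correlation between
residual maps and strain patterns that motivates residual-map fusion.
Per-sample length jitter scales with the template noise so the
zero-noise/single-subject configuration produces bit-identical samples per
class.

What passing these benchmarks shows: the pipeline's algorithmic parts are
correct (oracle agreement, analytic-map recovery, exact invariances), the
decoder can learn separable multichannel temporal patterns to ≥ 95 % test
accuracy from a few hundred samples, distillation retains accuracy within a
few points, and LoRA adapts with < 10 % of parameters without touching base
weights. What it does not show: performance on real throat recordings —
real strain signals have richer within-class variability, sensor artifacts,
and coarticulation effects that smooth Fourier templates do not model, so
the reported synthetic accuracies are upper bounds on, not estimates of,
real-world performance.

## Problem sizes used by the benchmarks

The standard benchmark dataset is 26 classes × 10 samples over 5 subjects
(260 sequences, 8 channels); training uses 182 samples with 26 validation
and 52 test. Strain-map fidelity uses a 9 × 13 marker layout under four
random deformations. These sizes keep a full run of the suite and the
acceptance script within a few minutes on a single CPU while leaving every
measured contract comfortably away from its tolerance.

## Known limitations

* The homography model cannot represent non-planar or strongly local
  deformations; local displacements enter the simulator but the estimator
  fits a single global H per frame pair (per the initial→current
  convention; incremental chaining is not implemented).
* Positional matching fails beyond pitch/2 inter-frame displacement.
* The VAD assumes quiet baselines; overlapping utterances closer than one
  window merge.
* The autodiff engine is single-threaded float64 numpy; it is sized for
  desk-scale models, not GPU-scale training.
* DTW is O(T²) per pair; the pairwise matrix dominates clustering cost for
  long sequences (use the optional band for long inputs).
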