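# Methods

`sozloc` implements a hybrid sorter for independent components (ICs) of
resting-state fMRI.  ICA of rs-fMRI in refractory-epilepsy cohorts yields
hundreds of components per patient, of which roughly half reflect
measurement noise, ~43% normal resting-state networks (RSN), and only a few
percent the seizure onset zone (SOZ).  The extreme rarity of SOZ ICs is
what defeats purely supervised classifiers; the method therefore combines
a data-driven arm for the well-populated noise class with an
expert-knowledge arm for the rare-class distinction.

## The two arms and their fusion

**DL arm (noise detection).**  RSN and SOZ ICs are relabeled to a single
non-noise class and a 2-D CNN is trained on the resized IC montage images
(270 x 470 x 3, intensities scaled to [0, 1]).  The architecture uses the
tuned configuration: three 3 x 3 convolution layers with 64, 64 and 256
filters, each followed by 2 x 2 max pooling; a 704-unit dense ReLU layer
with dropout 0.33; a sigmoid output trained with binary cross-entropy and
Adam at learning rate 1e-4, with early stopping on validation loss (20%
split, patience 5) and best-epoch weight restoration.  The network is
implemented directly on numpy (im2col convolution, explicit backward
passes, Adam); a numerical-gradient test pins the backward pass to the
forward pass.  All randomness — weight init, shuffling, dropout, the
validation split — derives from one seeded generator, so training is
bit-reproducible.  Inputs are standardized against the mean training image
before entering the network: the montages are dominated by identical dark
anatomy, and centering makes the activation geometry (the class signal)
the salient input.  Inference disables dropout; the decision threshold is
0.5 with ties going to non-noise.

**EKI arm (RSN vs SOZ).**  Four expert features form the vector `F_ex`:

1. `n_clusters` — cluster count/asymmetry score in [0, 1].  With `m` the
   median per-slice count of retained activation clusters (over slices
   with at least one) and `a` the fraction of cluster pixels on the
   dominant side of the slice midline, the score is `max(0, 2a - 1) / m`:
   1 for a single fully one-sided cluster (the SOZ archetype), 0 for
   mirrored symmetric activation (the RSN archetype).
2. `wm_ventricle` — fraction of retained clusters that both intersect the
   white-matter contour (dilated by 1 px; the contour is a 1-px path) and
   reach the ventricular region, capturing "activation extending from gray
   matter through white matter into the ventricles".
3. `activelet_gini` — Gini sparsity of pooled 4-level undecimated wavelet
   detail coefficients of the BOLD signal.
4. `sine_gini` — Gini sparsity of the in-band (0.01-0.1 Hz) Fourier
   magnitudes.

Each RSN/SOZ training IC contributes `F_hat = F_ex / ||F_ex||` with target
y = -1 (RSN) or +1 (SOZ).  SMOTE balances the rare SOZ class by linear
interpolation between a minority sample and one of its k nearest minority
neighbors (k = 5, clipped to minority size - 1).  Interpolation acts on the
already-normalized vectors, so synthetic points lie exactly on chords of
the unit sphere (norm <= 1) and are flagged as synthetic; only real pairs
carry the unit-norm invariant.  The weight vector omega minimizes
`sum_i (1 - y_i omega . F_hat_i)^2` subject to `sum(omega) = 1`, solved in
closed form by a null-space parametrization with an SVD-based minimum-norm
solution (exactly collinear features — which arise naturally when two
features separate the classes identically — fall back to an even split
rather than exploding).  Omega is not constrained non-negative.  An IC
scores `rho = omega . F / ||F||`; the EKI label is SOZ iff rho > 0, the
sign rule induced by the +/-1 coding.  The feature with the largest
contribution `omega_j F(j)` is reported as the explanation of a SOZ call.

**Fusion.**  If the CNN says non-noise, the EKI label stands.  If the CNN
says NOISE, only a high-confidence EKI SOZ call overrides — strictly
rho > 0.9 — otherwise NOISE stands.  For each final-SOZ IC the SOZ is
localized as its largest retained activation cluster across slices (ties:
lowest tile index, then lowest centroid row); SOZ ICs without any retained
cluster are flagged unlocalizable rather than silently dropped.

## Image processing

Montages are located, not assumed: slice tiles are found by normalized
cross-correlation against a packaged synthetic slice template (generated
in code, no data file).  Correlation runs at 4x reduced resolution —
only approximate origins are needed — and each origin is then refined by
centering the thresholded (hole-filled) brain structure in its tile
window, which recovers origins to +-1 px even where the correlation
surface plateaus (slices smaller than the template).  Tiles are ordered
base-to-apex row-major; the first third of the order counts as base
slices, the only ones where a ventricular region is computed.

Activation pixels are identified by a warm-color dominance rule
(R >= 180, R > G + 20, G > B + 10); grayscale anatomy can never satisfy
it.  Anatomy is extracted in the stated two-pass protocol: activation
pixels are first replaced by the value of their nearest non-activation
pixel (distance-transform interpolation), then contours are traced on the
thresholded Sobel gradient magnitude of the cleaned slice.  The longest
contour is the brain boundary; the white-matter contour is the longest
interior contour whose enclosed area is well below the boundary's (the
Sobel ridge yields nested contour pairs per edge, so the inner twin of the
boundary edge must not count as interior structure; ties break by larger
enclosed area).  The ventricular region is the set of dark pixels enclosed
by brain tissue that lie on no traced contour.

DBSCAN follows the stated semantics exactly: a pixel is core iff it has
strictly more than `v_min` neighbors (excluding itself) within `epsilon`;
core points within `epsilon` merge; border points attach to the *nearest*
core point (ties: lowest index); everything else is discarded.  Defaults
`epsilon` = 2.0 px (8-connected scale) and `v_min` = 4 are package choices
— the method names but does not value these parameters — and both are
exposed in the configuration.  Only clusters strictly larger than 135 px
are retained.  An O(n^2) brute-force expansion serves as the test oracle.

## The synthetic cohort generator

No public data exists for this task (the clinical dataset is restricted),
so the generator is a first-class module that emulates the three class
archetypes on a 46-tile montage (6 x 8 grid, 118 x 125 px tiles, native
709 x 1006):

* **SOZ** — an activation "finger" from the cortical band across the
  white-matter contour into a ventricular hole, strictly one hemisphere,
  on 1-4 adjacent base slices.  Hemisphere, cortical focus angle, slice
  range and finger width are drawn *per patient* (individual SOZ
  expression varies widely across patients; within a patient ICs only
  jitter around the focus).  Under leave-one-patient-out evaluation a test
  patient's SOZ geometry is therefore never seen in training — the
  property that makes the rare class hard for a purely supervised learner
  while leaving the abstract expert features invariant.
* **RSN** — 1-2 blob pairs mirrored across the slice midline in the
  cortical band (normalized radius 0.55-0.95), at any slice depth; they
  never reach the ventricles.
* **NOISE** — rim arcs straddling the brain boundary (one-sided in 70% of
  ICs, the morphology of motion artifact), sub-threshold speckle, and
  occasional off-brain blobs.

Time courses (600 samples, TR 2 s): SOZ = 2-4 well-separated in-band
sinusoids (sparse spectrum); RSN = 25-40 in-band components (dense);
NOISE = white noise + drift + sharp spikes.  A small noise floor keeps
every series non-constant.

A `separation` knob in [0, 1] controls how cleanly ICs obey their class
rules (1 = textbook; lower values mix spectra and inject rule violations
such as mirrored SOZ ghosts or interior noise blobs).  It exists to make
parameter-recovery experiments gradable and has no counterpart in real
data.  Generation is a pure function of (config, seed).

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: real IC montages have anatomical variation
across subjects, registration error, partial-volume and vascular
confounds, smoothly graded activation (ours is binary warm overlay), and
expert labels with inter-rater disagreement.  Parameter recovery on this
substrate validates the machinery (features, fit, fusion, evaluation
harness), not clinical performance.

## Evaluation

Cross-validation is leave-one-patient-out: each fold trains both arms on
all other patients and predicts every IC of the held-out patient.  Metrics
are per-IC SOZ-vs-rest (precision, sensitivity, accuracy, F1 = harmonic
mean); a patient-level sensitivity (any correct SOZ IC per patient) is
reported alongside, since the clinical question is patient-level.
Subgroup breakdowns use the generator's demographic tags, which are
sampled marginals with no biological meaning — they exercise the report
shape only.  Significance machinery: a KS check of normality per method's
subgroup metrics (standardized with estimated moments, hence
conservative), then a one-sided two-sample t-test; identical samples are
defined to give p = 0.5, zero-variance non-equal samples p -> 0/1 with a
degeneracy flag.

The knowledge-ablation suite reruns the full LOOCV with one expert feature
removed at a time, reusing the per-fold CNN arm (it does not depend on the
features).  On the textbook cohort, removing the white-matter-overlap
feature collapses precision: with it gone the weight mass shifts to the
cluster-asymmetry feature, which one-sided rim noise also scores highly,
so the rho > 0.9 override starts promoting noise ICs to SOZ.  This
reproduces the qualitative ranking reported on clinical data, where the
white-matter rule is the single most influential knowledge component.

The 3-class baseline ("labels only") is the same CNN backbone with a
softmax head and inverse-frequency class weights, evaluated on the same
folds.

## Problem sizes and numerical choices

The standard study runs 10 patients x 100 ICs (51/43/6% class mix,
matching the reported distribution) with the `small` CNN configuration:
54 x 94 inputs (4x local-mean prefilter + bilinear), filters (8, 16, 32),
dense 64, learning rate 1e-3, <= 20 epochs.  These sizes keep a full
study (feature extraction, 10-fold LOOCV of both models, ablation) in the
tens of minutes on one CPU; the full-resolution architecture remains the
default configuration of the CNN module.  Degenerate inputs are defined,
not crashed on: all-zero feature vectors score rho = 0 with a warning,
all-zero Gini inputs score 0, saturated tiles interpolate to background,
montages matching no template tile return an empty slice list with a
warning.

A stated dominant-frequency criterion above 6 Hz is not implementable at
TR 2 s (Nyquist 0.25 Hz); the dominant in-band frequency is computed as a
diagnostic only and the feature vector carries the two Gini sparsity
measures.

## Known limitations

* The activelet basis is approximated by a B-spline biorthogonal wavelet
  (`bior2.2`) under the same 4-level a-trous structure; the interface
  accepts any pywt wavelet name so a faithful exponential-spline basis can
  be dropped in.
* "White matter" and "ventricle" are contour-defined proxies on rendered
  montages, not segmentations.
* Clustering is per-slice 2-D; no 3-D linking across slices.
* The standalone EKI decision uses sign(rho); the 0.9 threshold is
  reserved for the fusion override.  Whether the original confidence for
  the override used a differently normalized score is unknown; the same
  rho serves both roles here.
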