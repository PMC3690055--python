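# Methods

`eegcam` detects and excises head-movement artifacts in single-channel
(channel-averaged) headset EEG by fusing two synchronized streams: the EEG
itself, sampled at 128 samples/s, and the image sequence of a frontal
(scene-facing) camera at 30 frames/s.  A head rotation moves every pixel of
the frontal view and simultaneously disturbs the electrode–scalp contacts,
so the two modalities carry complementary evidence about the same event.

## Features

**EEG.**  The stream is scanned with a 128-sample window moved one sample
at a time (127-sample overlap).  Each window is normalized — mean removed,
then min–max mapped onto [−1, 1] — and yields:

* 12 frequency-domain features: the mean DFT magnitude in the fixed bands
  3–15, 4–6, 5–7, 6–8, 7–9, 8–10, 9–11, 10–12, 15–30, 20–30, 51–64 and
  59–61 Hz.  At 128 samples / 128 samples/s the DFT bins fall on integer
  hertz, and a band averages its bins inclusively.  Averaging (rather than
  summing) keeps wide and narrow bands on one scale.  No window taper is
  applied.
* 13 time-domain features: kurtosis and skewness (raw standardized moments
  with population variance, so a normal signal has kurtosis ≈ 3), RMS
  amplitude defined as the peak absolute value divided by √2, the
  zero-crossing count (strict sign change between adjacent samples; exact
  zeros neither count nor interrupt a crossing), minimum, maximum, the
  variance and zero-crossing counts of the first and second differences,
  and the Hjorth parameters activity = var(x), mobility =
  √(var(Δx)/var(x)) and complexity = mobility(Δx)/mobility(x).

Because every valid window is min–max normalized, three of the thirteen
time features are constant by construction (minimum ≡ −1, maximum ≡ +1,
peak/√2 ≡ 1/√2).  They are computed and reported faithfully; the
z-scoring step ahead of the classifier guards constant columns, so they are
harmless.

**Camera.**  For each consecutive frame pair: the mean absolute pixel
difference; the same difference computed on Sobel edge-magnitude maps (two
3×3 masks, L2-combined, replicate borders); and the average magnitude and
count of sparse optical-flow vectors.  The flow is the classic KLT scheme:
Shi–Tomasi corners (minimum structure-tensor eigenvalue, quality-thresholded
greedy selection with a minimum separation) tracked by iterative
Lucas–Kanade minimization of the windowed squared residual between frames,
coarse-to-fine over an image pyramid.  Differences are means over pixels,
making the features resolution-independent; color frames are reduced to
grayscale with ITU-R 601 luma weights on load.  The tracker is implemented
in-package with numba-compiled kernels; the per-pair public functions and
the batched per-trial driver share the same kernels and are tested for
exact agreement.

Tracking defaults (up to 400 corners, quality 0.01, 5 px minimum distance,
21×21 window, 3 pyramid levels, 20 iterations, ε = 0.01 px) follow common
KLT practice.  The synthetic benchmark uses a lighter configuration
(40 corners, 11×11 window, 2 levels, quality 0.03): its scenes move
globally, so a few well-spread corners measure the motion just as well at a
fraction of the cost.

## Synchronization

Features are assembled at the camera cadence.  Frame *i* (*i* ≥ 1) carries
the motion features of the pair (*i*−1, *i*) and the EEG features of the
epoch whose end time is nearest the frame timestamp (ties to the earlier
epoch).  Frames earlier than the first complete epoch — the first second of
a trial — are dropped with a logged count.

## Classifier

Feature vectors are z-scored with training-fold statistics (RBF kernels on
mixed-unit features require a common scale).  Fisher LDA is then fit
without regularization: with empirical class priors *q_j*, within-class
scatter M_W = Σ q_j M_j and between-class scatter
M_B = Σ q_j (m_j − m)(m_j − m)ᵀ, the projection directions solve the
generalized eigenproblem of (M_B, M_W), sorted by non-increasing
eigenvalue (pseudo-inverse fallback, logged, if M_W is singular).  With two
classes M_B has rank one, so only the leading direction is theoretically
discriminative; the trailing directions form an M_W-whitened complement
whose internal order is numerically arbitrary.  They are retained anyway
and the dimension count k is chosen empirically, because a kernel
classifier downstream is rotation-invariant: at larger k the projection
approaches an information-preserving whitening, which lets the SVM exploit
class-conditional *covariance* differences (the movement class is far more
dispersed than the still class) that no single linear direction carries.
In practice the selected k is 1 for the plain-LDA rule and larger for the
LDA+SVM pipeline.

The classifier proper is a soft-margin SVM (scikit-learn's SVC does the
fitting) with Class 1 (still) mapped to −1 and Class 2 (movement) to +1.
The kernel family and parameters are grid-searched: linear; RBF
exp(−r‖x−x′‖²); polynomial (r xᵀx′ + c)^d; sigmoid tanh(r xᵀx′ + c);
soft-margin cost C ∈ {1, 10}.  The deployed decision value is the explicit
support-vector expansion Σ a_k y_k K(x_k, x) + b computed from the stored
support set, cross-checked in tests against the library's decision
function.  The final label is Class 2 iff this value strictly exceeds a
threshold tuned to minimize the average of the Type-1 and Type-2 error
rates; ties at the threshold go to Class 1, so EEG is only rejected on
strict evidence.

**Model selection.**  The dimension count, kernel and threshold are all
chosen on the training fold alone, with an inner split that holds out
*whole subjects* (fallback: whole trials, then temporal blocks within a
trial).  A random sample split would be badly leaky here: adjacent
instants share 127 of their 128 EEG samples, and instants from a seen
trial share that trial's texture, pan realization and EEG envelopes, so
overfit kernels would look spuriously good at selection time.  For the
LDA+SVM pipeline the dimension count and the kernel are selected jointly —
every (k, kernel) pair is fit on a capped balanced subsample and scored by
its threshold-tuned average error on the held-out part, with near-ties
(within 0.2 points) resolved toward the smallest k and simplest kernel.
The deployed model is refit on the inner-training part and its threshold
tuned on inner-validation scores, never on scores of samples the model was
fit on.  The plain-LDA rule selects k with the centroid score
(‖z−c₁‖² − ‖z−c₂‖², a linear function of z) that also serves as its
decision value; it almost always settles on k = 1.  Note that at k = 1 any
monotone score gives the same thresholded rule, so the LDA+SVM pipeline
can exactly tie the plain-LDA rule when nothing beyond the leading
direction helps.

**Evaluation.**  Type-1 error = % of still instants flagged as moving;
Type-2 error = % of moving instants missed; average error = their mean.
Accuracy is measured with two-fold cross-validation whose folds are whole
trials (every subject's first trials vs second trials), trained one way,
swapped, and averaged.  ROC curves sweep the decision threshold over the
unique decision values; the area (trapezoid rule, ties contributing half)
equals the Mann–Whitney pairwise estimator, which the tests assert.

**Rejection.**  Each frame's label governs the EEG interval [frame time,
next frame time); consecutive movement intervals merge into rejected
sections, reported as a half-open-interval table alongside the retained
EEG segments.

## Synthetic data

No public recordings exist for this task, so the package ships a
first-class generator that reproduces the class-conditional structure the
detector consumes; it is phenomenological, not biophysical.

*EEG*: a sum of random-phase sinusoids in a low group (4–12 Hz, dominant
at rest) and a high group (18–29 Hz plus a broadband 15–35 Hz component,
boosted by movement), a small 60 Hz mains component, and 1/f background
noise.  Movement trials scale the high group up (×2.2 by default) and the
low group down (×0.55).  Each band group is amplitude-modulated by a slow
log-Ornstein–Uhlenbeck envelope (τ = 2 s, σ = 0.3), and subjects carry
lognormal gains on every component and on the class-2 scaling factors, so
epoch-level spectral contrast fluctuates and overlaps across people — which
is why the EEG-only detector is mediocre, as single-channel headset
recordings are.

*Video*: a fixed per-subject smoothed-noise texture viewed through a crop
window.  Still trials have sub-pixel tremor (AR(1) jitter, ~0.015 px/frame
innovations) plus occasional smooth posture adjustments of a few pixels —
nobody holds a pose perfectly, and these "slight movements" are the
realistic source of false alarms.  Movement trials add a sinusoidal
horizontal pan emulating natural yaw (peak speed 4 px/frame, ~0.25 Hz)
whose phase freezes during random momentary holds (~0.08 events/s of
0.6–1.2 s): a person rotating "naturally" pauses now and then.  Pan
reversals and holds are the instants where the camera alone is blind and
trial-wide EEG character must break the tie — the structural reason fusion
and a nonlinear classifier beat either ingredient.  Frames are rendered by
bilinear texture sampling and quantized to 8 bits.

Trials are 47 s (mid-range of the 45–50 s protocol), two still and two
moving trials per subject, ten subjects per session, labels constant per
trial.  Identical configuration and seed reproduce every sample, frame and
manifest bit for bit.

What passing tests on this generator do **not** show: robustness to real
scenes (depth parallax, lighting, rolling shutter), to eye-blink or other
non-movement EEG artifacts, to multi-channel electrode-specific effects, or
to movement types other than horizontal yaw.

## Problem sizes and numerical choices

The end-to-end benchmark runs ten sessions (seeds 0–9), extracts features
at every frame instant (~55,000 vectors per session) and evaluates four
conditions under two-fold CV.  Model fitting thins training instants to
every 8th frame (adjacent instants are ~duplicates; evaluation is always at
full cadence), caps kernel grid-search fits at 1,200 balanced samples and
the final refit at 4,000, and uses the compact linear+RBF grid.  These
sizes were chosen so a full benchmark completes in minutes on one core
while test-fold error estimates (two folds × ~27,000 instants) stay tight.

Numerical details: min–max normalization maps extremes to ±1 exactly;
degenerate (constant) windows are flagged and excluded rather than imputed;
the threshold search enumerates midpoints of consecutive unique decision
values plus sentinels, breaking ties toward zero; LDA directions are
sign-fixed so the movement class projects positively; the RBF kernel is
evaluated with the quadratic-expansion distance (clamped at zero) in row
blocks to bound memory.

## Known limitations

* The trailing LDA dimensions are meaningful only through the whitening
  they inherit; their individual ordering is numerically arbitrary.
* The per-trial labels mean partially contaminated trials are out of scope.
* The tracker assumes mostly-translational scene motion between consecutive
  frames (true for yaw at 30 frames/s); large rotations or motion blur
  would degrade it.
* With the paper-faithful normalization, three time-domain features are
  constants and carry no information.
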