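# Methods

This note documents the models, the synthetic phantom, the numerical
choices and the known limitations of the `thermoseries` pipeline.

## Physical models

**Surface law.** A buried heat source of intensity `q` (W) at effective
depth `deff` produces the surface temperature
`T(a) = Te + q / (4π h0 (deff² + a²))` at radial distance `a` from the
source's surface projection.  `deff = d` is the point-source form (the
default forward/inverse pair, because the D-I-R inversion is its exact
algebraic inverse); `deff = d + R` is available behind the `use_radius`
flag for a finite spherical source.  Constants: `h0 = 8.77 W·m⁻²·°C⁻¹`,
`Qm = 418.6 W·m⁻³`, `At = 1` (dimensionless scale; the radius estimate
`R = (q/(Qm·At))^⅓` is isolated in one function so an alternative reading
of the radical can be swapped in).  The law is treated as the operational
forward model exactly as stated; no transient 3-D bio-heat solver is
attempted (out of scope by design).

**Recovery law.** Post-stress rewarming is `T(t) = T∞ − (T∞ − T0)e^(−t/τ)`.
Fitting uses `scipy.optimize.curve_fit` with initialization T0 ← first
sample, T∞ ← last sample, τ ← span/3, bounds τ ∈ (0, 100·span].  This
initialization is already close for any monotone rewarming curve, and the
returned fit never has a larger residual sum of squares than it (the fit
falls back to the initialization in the pathological case).  Flat series
return T0 = T∞ with τ flagged unidentifiable rather than an arbitrary
number.  The frame clock is 20 frames at 15 s (five minutes); the
synthesize-and-refit reference computation uses 20 evenly spaced points
over 300 s.

**D-I-R extraction.** Per frame: the hotspot is the RoI argmax (ties →
smallest row-major index); `T(a)` is the mean over the annulus of masked
pixels within half a pixel pitch of the metric radius `a = 0.0168 m`
(a line mode sampling the two horizontal points at ±a exists for
comparison, but the annulus mean is the default since the model is radially
symmetric); `Te` defaults to the 10th percentile of masked temperatures — a
surround-tissue proxy that also makes `q` and `d` invariant to adding a
constant to the whole frame.  A constant override is available.  Note the
frame-based estimator is biased upward by the source's own long radial
tail, so inversion accuracy tests pass the known baseline as the override;
in the classification pipeline only the discriminative value of the
descriptors matters, not their absolute calibration.  Degenerate profiles
(Tmax ≤ T(a) or T(a) ≤ Te, i.e., no thermal contrast) yield missing
descriptors that are carried forward from the previous frame (leading
gaps back-filled, an all-degenerate series falls back to q = 0, d = a),
keeping every series at length M with a logged flag.  Depth is computed
per frame by default (keeping the V = 5 × M = 20 tensor); a per-subject
median collapse is available since a real source's depth is static.

## Synthetic phantom

Each frame is the sum of four terms, clipped to the physically plausible
20–40 °C band:

1. a spatially constant rewarming baseline with class kinetics
   control (T0 32.14, T∞ 32.63 °C, τ 57.76 s) and
   cancer (32.69, 33.80 °C, 56.26 s) — the fitted group curves;
2. a hotspot bump from the point-source law, `q = 0.132 W, d = 0.02 m`
   for cancer, offset 8 px diagonally from the RoI center (asymmetry), and
   a near-zero `q = 0.008 W` centered source for controls ("hot spots
   absent").  The intensity rises with the class rewarming factor above a
   floor of 0.3·q, so the intensity series is informative over time;
3. a smooth heterogeneity field: Gaussian-blurred white noise (blur 4 px),
   zero-mean over the RoI, scaled to sd 0.90 °C (control) / 0.95 °C
   (cancer) — drawn once per sequence so spatial structure persists across
   frames;
4. i.i.d. Gaussian sensor noise, sd 0.05 °C, redrawn per frame.

Geometry: 96×96 grid at 1 mm/pixel (so a = 0.0168 m spans ≈17 pixels
inside a disk RoI of radius 0.47·grid), 25 subjects per class, balanced,
deterministically shuffled and seeded via `numpy` SeedSequence spawning.

What the phantom does **not** emulate: breast anatomy and curvature,
emissivity and radiometric camera effects, bilateral asymmetry between two
breasts, motion, or the acquisition-side cooling criterion (sequences
start at post-stress T0 directly).  Classifier scores on this phantom
therefore demonstrate that the pipeline recovers the injected group
structure — not clinical performance.  The default contrast is well
separated by construction, which is why both classifiers reach AUC 1.0 on
it and why feature-set comparisons come out statistically equivalent.

## Classifiers

**Time Series Forest.** Per tree and variable, k intervals (k defaults to
round(√M) = 4; the interval length is uniform on [ℓmin, M], then the start
uniform over admissible positions).  Features are (mean, sd with N−1,
OLS slope) per interval, concatenated to length 3kV.  Trees are grown to
purity with exhaustive entropy-gain splits at midpoints; ties break toward
the first feature and smallest threshold, with an optional secondary
margin comparator (off by default).  No bagging: interval randomness is
the diversity mechanism.  Votes average to a score; exact vote ties go to
control — conservative for a screening score.  Temporal importance credits
each split's sample-weighted gain to every time index of the split
feature's interval and normalizes to unit mass.  The hyperparameter grid
(trees 100/200/300 × ℓmin 3/5/7) is searched by stratified 5-fold CV mean
accuracy with ties toward the smaller model.  The TSF path consumes raw,
unstandardized series.

**LSTM.** Implemented in NumPy inside the package: a literal per-equation
gate cell serves as the reference implementation, and the batched
training layer (fused 4H×(H+D) weights, full backpropagation through
time) is verified against it to 1e-5 over random weights; analytic
gradients are verified against numerical differentiation in the tests.
Architecture: LSTM(64) → dropout → LSTM(32) → batch norm → dropout →
dense(16, ReLU) → sigmoid, BCE loss, Adam.  Dropout defaults to 0.5
(config-exposed, 0.1 also smoke-tested).  Unstated training
hyperparameters are conventional, deliberate choices: learning rate 1e-3,
batch 16, max 200 epochs, patience 20, Glorot initialization with
forget-gate bias 1.  Per CV fold, a stratified 80/20 inner split of the
training fold provides the early-stopping validation set; standardization
moments are fitted on the fold's training subjects only and applied to
everything else (the leakage-safe reading of "normalized independently
within each fold"; a global mode is not the default).  Augmentation
(original + one noise copy at sd 0.05 + one shift copy with s ∈ {1, 2},
exactly 3× total, the inclusive reading of "expanded by a factor of 3")
applies to the inner-training partition only.  The end-to-end test and the
demo run the LSTM at a reduced epoch budget (60, patience 10), a problem
size at which the separable phantom converges comfortably.

## Evaluation and statistics

Positive class is cancer; confusion rows are (control, cancer) so the
normalized diagonal reads (specificity, sensitivity).  AUC is the
rank-based probability (verified against brute-force Mann–Whitney pair
counting); the mean ROC is vertically averaged at 101 FPR grid points.
The Friedman statistic is computed in-package (within-fold average ranks
with the standard tie correction, p from χ² with k−1 df) and is verified
against `scipy.stats.friedmanchisquare`; pairwise Wilcoxon signed-rank
tests use scipy's exact method — at n = 5 folds the asymptotic
approximation is unreliable — verified against full sign-pattern
enumeration.  Raw p-values are reported; no multiple-testing correction.

## Determinism and degenerate inputs

Every stochastic component (phantom, interval sampling, augmentation,
weight initialization, batch shuffling, dropout) draws from a seeded
`numpy` Generator; reruns with the same seed are bit-identical, including
the LSTM path.  Zero-variance features are floored at sd 1e-12 with a
warning; empty confusion rows become NaN rows; single-class truth flags
AUC as NaN; an empty annulus reports the achievable maximum radius.

## Known limitations

* The surface law is a steady-state point-source approximation; recovered
  `q` and `d` are effective parameters, not calorimetric measurements.
* The frame-based `Te` estimator biases the inversion (see above); absolute
  descriptor calibration on real data would need a surround-tissue
  measurement.
* Only the plain-text matrix dialect is read; real-database ingestion is
  an adapter point, not a tested path.
* Single-threaded by design: seed-stable results take precedence over
  training speed at this problem size.
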