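# Methods

`spiraltremor` turns a photograph or scan of a hand-drawn Archimedean
spiral into a tremor-deviation signal, summarizes that signal with
frequency-domain and pencil-stroke features, and classifies the drawing as
*healthy* vs *parkinson*.  This note documents the model, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## The spiral model and the deviation signal

The guided drawing is an Archimedean spiral, r = a·θ in polar coordinates:
the radius grows by a constant `a` (px/rad) per radian, so successive turns
are evenly spaced.  The clinical drawing task uses 4.5 revolutions with a
75 mm maximum radius, drawn clockwise.  A steady hand produces a trace
close to this law; Parkinsonian rest/action tremor superimposes a roughly
sinusoidal radial oscillation, classically in the 4–6 Hz band.

Processing stages:

1. **Binarization** — Gaussian blur (5×5 kernel, σ ≈ 1.1) followed by
   adaptive thresholding against a local Gaussian-weighted mean
   (block 11 px, offset 2).  Drawings must be dark-on-light; inputs whose
   global mean is below mid-gray are rejected as wrong-polarity rather than
   silently inverted.
2. **Thinning** — Zhang–Suen morphological thinning
   (`skimage.morphology.skeletonize`, method `"zhang"`) reduces the stroke
   to a one-pixel-wide skeleton.
3. **Center** — the largest contour's area centroid gives a coarse center.
   For a spiral with a fractional turn count the area centroid is biased by
   the lopsided final half-turn (≈ 2a, i.e. ~21 px at default scale), so a
   refinement step regresses the unwrapped distances on cos α and sin α of
   the raw polar angle — the first-order signature of a center offset — and
   iterates three times, reaching sub-0.2 px accuracy on rendered spirals.
   Refinement is on by default (`PipelineConfig.refine_center`).
4. **Unwrapping** — the skeleton is walked pixel-by-pixel from the end
   nearest the center outward; each pixel contributes its Euclidean
   distance to the center and its polar angle.  Angles are cumulatively
   unwrapped (successive increments kept in (−π, π)) starting from the
   *outer* end, where the angle is well-conditioned; the few pixels within
   2 px of the center, whose polar angle is undefined at pixel resolution,
   get angles extrapolated from the local angle–distance trend.  Skeletons
   with junction pixels (Rutovitz crossing number ≥ 3) — self-intersecting
   or touching drawings — raise `UnusableSpiralError` and are excluded, not
   repaired.  A raw ≥3-neighbour test would be wrong here: Zhang–Suen
   staircase corners routinely have three neighbours without branching.
5. **Line of best fit** — a cubic smoothing spline of distance vs unwrapped
   angle with smoothing parameter s = n·N, where n is the trace length and
   N (default 10) the smoothing scale.  N = 0 interpolates; larger N
   idealizes more aggressively.  The deviation signal is the pointwise
   difference between traced distances and the spline.
6. **Spectrum** — the deviation is treated as a uniformly sampled time
   series with fs = n / 10 s (the nominal drawing duration), transformed
   with an FFT; magnitudes are divided by n and truncated to the positive
   half.  Magnitudes are not doubled and no windowing or detrending is
   applied; the spline subtraction already centers the signal and the DC
   bin is retained and participates in the peak search.

## Features

Frequency features (per drawing): peak magnitude and peak frequency of the
spectrum (lowest frequency wins ties); a noise threshold of twice the mean
spectrum magnitude rounded to three decimals; SNR = mean power of the bins
strictly above the threshold over mean power of the rest, minus one;
population variance of the above-threshold magnitudes; and bandwidth, the
count of above-threshold bins.  "Exceeds" is strict; SNR and variance are
NaN when no bin clears the threshold, and SNR is +inf when the noise power
is exactly zero.  NaN values flow into the feature table and are removed by
row cleaning, never guessed.

Pencil features: a global threshold T = mean − (255 − mean) = 2·mean − 255
(clamped to [0, 255]) isolates the pencil pixels of the grayscale image.
*Pressure* is their mean intensity (darker = heavier).  *Thickness* is the
pencil pixel count divided by the summed sub-pixel arc length of the stroke
boundaries (outer and hole boundaries both counted by default,
configurable).  Since a ribbon's boundary is about twice its path length,
thickness is a consistent relative width measure, not a literal width.

## Classification

Feature tables (F = 5 frequency features, P = 2 pencil features, FP = all
7) are standardized and classified.  Six families are supported: decision
tree, random forest, SVM, XGBoost, AdaBoost on depth-1 trees, and LightGBM
(grids in `estimators.DEFAULT_GRIDS`, all overridable; LightGBM uses
`min_child_samples=5` because the stock 20 collapses trees to constants on
cohort-sized tables).  Hyperparameters are chosen by grid search with
stratified 5-fold CV scored on accuracy, ties resolved in declared grid
order.  The scaler and classifier live inside one sklearn `Pipeline` placed
*inside* the CV loop, so each fold's standardization statistics come from
that fold's training rows only — no leakage from validation folds.  The
winning grid point is refit on all training rows.  The positive class is
`parkinson`; reports carry the confusion matrix, per-class
precision/recall/F1, and support-weighted averages, as percentages rounded
to two decimals.

Rotation is the only augmentation (−45° to 165° in 15° steps, bilinear,
white fill; the 0° copy is bit-identical to the input).  Scaling would
erase micrographia information, shifting is void once the center is
detected, and blur/brightness changes corrupt the pencil features.  The
protocol runner augments the training split only: evaluating on rotated
copies of training drawings would inflate accuracy.

## Synthetic drawings

`simulate` renders r(θ) = a·θ + A·sin(2π·f·t(θ)) with drawing time t
advancing uniformly with arc length over 10 s — a constant drawing speed.
Because the spectrum stage also assigns each traced pixel a uniform time
step, a tremor injected at f Hz reappears at f Hz, giving an unambiguous
ground truth.  The curve is sampled densely (sub-pixel steps), thickened to
the stroke width by a Euclidean distance threshold without anti-aliasing
(so pencil thresholds are predictable), and painted at a configurable
intensity with optional per-pixel Gaussian jitter.  The default scale maps
the 75 mm guide radius at 4 px/mm, giving a ≈ 10.6 px/rad on a 672 px
canvas and traces of ≈ 3 800 px (fs ≈ 380 Hz).

Cohort defaults: healthy drawings have sub-pixel tremor (A ≤ 1 px);
parkinsonian drawings draw A from 2.5–6 px and f from the 4–6 Hz tremor
band (a literature convention — the source imaging study does not report
its tremor band), with on-average darker and slightly thicker strokes
(heavier pressure).  Standard experiment sizes: 50+50 drawings per
replicate, 80/20 stratified split, 5 replicate seeds, grid-searched random
forest.

What the simulator does **not** emulate: pen lifts and retraces, in-air
gaps, micrographia progression, paper texture, scanner shading, drift in
drawing speed, or non-sinusoidal tremor.  Passing synthetic tests
demonstrates that the pipeline recovers known tremor parameters and
separates well-separated cohorts; it does not certify performance on real
clinical drawings, whose class overlap is far larger.

## Numerical choices and degenerate inputs

- Duplicate spline abscissae are averaged before fitting (smoothing splines
  need strictly increasing x); the spline is evaluated at every original
  trace point.
- Distances are exact Euclidean values; the trace-level quantization floor
  is ≈ 0.28 px RMS, white across the spectrum.  Consequently the null
  (tremor-free) bandwidth sits near the Rayleigh tail fraction exp(−π) ≈
  4.3% of bins — a flat-noise property worth knowing before interpreting
  bandwidth on near-perfect drawings.
- The smoothing law s = n·N caps the deviation RMS near √N ≈ 3.2 px: tremor
  amplitudes beyond ≈ √(2N) ≈ 4.5 px are partially absorbed by the line of
  best fit, so SNR saturates at large amplitudes.
- Blank pages, wrong-polarity images, fragmented or branching skeletons,
  and degenerate contours raise typed errors at the operation level; table
  building converts them to NaN rows, and prediction on such images returns
  `"unusable"` rather than a guess.
- All randomness (stroke jitter, cohort sampling, CV shuffling, stochastic
  learners) is seeded; identical seeds give bit-identical images and
  identical chosen hyperparameters.

## Known limitations

- One connected stroke per image is assumed; multi-stroke drawings with
  pen lifts produce fragmented skeletons and are excluded.
- Thickness depends on image resolution; compare it only within a cohort
  scanned at one scale.
- The 10 s nominal drawing duration is a population-level approximation;
  per-subject speed differences shift the absolute frequency axis.
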