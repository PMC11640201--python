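# spiraltremor

Tremor analysis and Parkinson's-disease screening from photographs of
hand-drawn Archimedean spirals — pencil and paper only, no tablet or
digital pen required.

Drawing a guided spiral (4.5 revolutions, 75 mm maximum radius) is a
classic motor test: Parkinsonian tremor leaves a 4–6 Hz radial oscillation
in the trace, and bradykinesia/rigidity alter stroke pressure and width.
`spiraltremor` extracts both signatures directly from a raster image:

1. the drawing is binarized (adaptive threshold) and thinned to a
   one-pixel skeleton (Zhang–Suen);
2. the skeleton is *unwrapped* from the spiral center outward into a
   distance-vs-angle trace, d_i = √((x_i−x_c)² + (y_i−y_c)²);
3. a cubic smoothing spline with s = n·N (N = 10) idealizes the trace —
   the line of best fit for r = a·θ — and the residual is the
   **tremor-deviation signal**, treated as a time series sampled at
   fs = n/10 s;
4. its single-sided, length-normalized FFT magnitude spectrum yields five
   frequency features (peak magnitude, peak frequency, SNR against a
   2×mean noise threshold, variance and bandwidth of the signal band), and
   grayscale intensity yields two pencil features (thickness, pressure);
5. a grid-searched classifier (random forest by default; DT, SVM, XGBoost,
   AdaBoost-DT and LightGBM also supported) with leakage-free fold-wise
   standardization labels the drawing *healthy* or *parkinson*.

A seeded synthetic-spiral simulator with known tremor ground truth
(r(θ) = a·θ + A·sin 2πf·t) makes every stage testable without clinical
data.  See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from spiraltremor import (SpiralSpec, render_spiral,
                          image_frequency_features, spiral_trace)

# a synthetic Parkinsonian drawing: 5 Hz tremor, 4 px amplitude
spec = SpiralSpec(tremor_amplitude=4.0, tremor_frequency=5.0,
                  intensity_jitter=6.0, seed=8)
image = render_spiral(spec)          # 672x672 uint8, dark spiral on white

trace = spiral_trace(image)          # unwrapped angle-distance series
feats = image_frequency_features(image)
print(f"n={trace.n_points}  peak {feats.peak_frequency:.1f} Hz "
      f"mag {feats.peak_magnitude:.2f} px  SNR {feats.snr:.0f}")
```

Output:

```
n=3922  peak 5.0 Hz mag 1.86 px  SNR 2387
```

The unwrapped trace has 3 922 pixels (fs ≈ 392 Hz), the spectral peak sits
exactly at the injected 5 Hz with magnitude ≈ A/2 ≈ 2 px, and the SNR in
the thousands says the tremor energy is sharply concentrated — a
tremor-free drawing of the same geometry gives SNR ≈ 4 and peak magnitude
≈ 0.02 px.

End-to-end on a cohort:

```python
from spiraltremor import make_labeled_set, build_feature_table, \
    clean_table, train_grid_search, evaluate

cohort = make_labeled_set(n_healthy=51, n_pd=51, seed=7)   # 102 drawings
table = clean_table(build_feature_table(cohort.images, cohort.labels, "FP"))
model = train_grid_search(table, algorithm="RF", seed=0)
```

There is also a CLI: `spiraltremor simulate | extract-features | train |
evaluate | predict | protocol` (the `protocol` subcommand runs the whole
augment → extract → grid-search → evaluate recipe on a
`{train,test}/{healthy,parkinson}` directory tree of PNG/JPEG drawings).

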