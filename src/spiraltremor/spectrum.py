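"""Line-of-best-fit spline, tremor-deviation signal, frequency spectrum.

The unwrapped distance-vs-angle trace is idealized by a smoothing cubic
spline (the "line of best fit").  Its smoothing parameter is tied to the
trace length,

    s = n_points * N,

with the smoothing scale N defaulting to 10 — small enough that the spline
follows the spiral's trajectory, large enough that it does not chase the
tremor.  The tremor-deviation signal is the pointwise difference between the
traced distances and the spline, treated as a uniformly-sampled time series
with sampling rate fs = n_points / draw_duration (drawing time approximated
at 10 s).  Its FFT magnitude, normalized by the signal length and truncated
to the positive half, is the spectrum the frequency features are read from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

from .unwrap import PolarTrace

__all__ = ["LobfConfig", "DeviationSignal", "Spectrum", "fit_lobf",
           "deviation_signal", "to_spectrum"]

SPLINE_DEGREE = 3


@dataclass(frozen=True)
class LobfConfig:
    """Configuration of the line-of-best-fit smoothing spline.

    ``smoothing_scale`` is the factor N in s = n_points * N; N = 0 gives an
    interpolating spline (zero deviation at the data points).
    """

    smoothing_scale: float = 10.0

    def __post_init__(self):
        if self.smoothing_scale < 0:
            raise ValueError("smoothing_scale must be >= 0")

    def smoothing(self, n_points: int) -> float:
        return float(n_points) * self.smoothing_scale


@dataclass
class DeviationSignal:
    """Per-point tremor deviation (px) with its synthetic sampling rate."""

    amplitudes: np.ndarray  # px
    angles: np.ndarray      # radians, x-axis of the deviation plot
    fs: float               # Hz

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.amplitudes.shape != self.angles.shape:
            raise ValueError("amplitudes and angles must be equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class Spectrum:
    """Single-sided, length-normalized magnitude spectrum."""

    freqs: np.ndarray   # Hz, starting at 0 (DC)
    mags: np.ndarray    # px, |FFT|/n
    n_signal: int       # length of the originating signal

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.mags = np.asarray(self.mags, dtype=float)
        if self.freqs.shape != self.mags.shape:
            raise ValueError("freqs and mags must be equal length")


def _strictly_increasing(x: np.ndarray, y: np.ndarray):
    """Sort by x and average y over duplicate x (spline abscissa contract)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ux, inverse, counts = np.unique(xs, return_inverse=True,
                                    return_counts=True)
    if len(ux) == len(xs):
        return xs, ys
    sums = np.zeros(len(ux))
    np.add.at(sums, inverse, ys)
    return ux, sums / counts


def fit_lobf(trace: PolarTrace, config: LobfConfig = LobfConfig()
             ) -> np.ndarray:
    """Evaluate the smoothing-spline line of best fit at every trace angle.

    The spline is cubic with s = n_points * smoothing_scale.  Duplicate
    angles are collapsed (averaged) before fitting; the returned array has
    one smoothed distance per original trace point.
    """
    x, y = _strictly_increasing(trace.angles, trace.distances)
    if len(x) < SPLINE_DEGREE + 2:
        raise ValueError("too few distinct angles for a cubic spline fit")
    s = config.smoothing(trace.n_points)
    spline = UnivariateSpline(x, y, k=SPLINE_DEGREE, s=s)
    return np.asarray(spline(trace.angles), dtype=float)


def deviation_signal(trace: PolarTrace, lobf: np.ndarray,
                     draw_duration: float = 10.0) -> DeviationSignal:
    """Tremor deviation: traced distances minus the line of best fit.

    The sampling rate is the number of trace points divided by the nominal
    drawing time (10 s), so each traced pixel is one time sample.
    """
    lobf = np.asarray(lobf, dtype=float)
    if lobf.shape != trace.distances.shape:
        raise ValueError("lobf length does not match the trace")
    fs = trace.n_points / float(draw_duration)
    return DeviationSignal(amplitudes=trace.distances - lobf,
                           angles=trace.angles.copy(), fs=fs)


def to_spectrum(dev: DeviationSignal) -> Spectrum:
    """Length-normalized single-sided FFT magnitude spectrum.

    mags = |FFT(x)| / n, truncated to the first floor(n/2) bins; the DC bin
    is retained.  Magnitudes are not doubled.
    """
    x = dev.amplitudes
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    mags = np.abs(np.fft.fft(x)) / n
    half = n // 2
    freqs = np.arange(half) * dev.fs / n
    return Spectrum(freqs=freqs, mags=mags[:half], n_signal=n)
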