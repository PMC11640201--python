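"""Frequency-domain and pencil-stroke features.

Frequency features (five, per drawing) are read from the single-sided
deviation spectrum:

* ``peak_magnitude`` / ``peak_frequency`` — value and location of the
  spectral maximum (lowest frequency wins ties; the DC bin participates).
* ``noise_threshold`` — twice the mean of all spectrum magnitudes, rounded
  to three decimals.  Bins strictly above it are "signal", the rest "noise".
* ``snr`` — mean signal power over mean noise power, minus one.
* ``variance`` — population variance of the above-threshold magnitudes.
* ``bandwidth`` — count of above-threshold bins.

Pencil features (two) come from grayscale intensity: a global threshold
T = mean - (255 - mean) isolates the pencil pixels; ``pressure`` is their
mean intensity (darker = heavier) and ``thickness`` the pencil pixel count
divided by the summed arc length of all stroke contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import find_contours

from .spectrum import Spectrum

__all__ = ["FrequencyFeatures", "PencilFeatures", "noise_threshold",
           "compute_snr", "extract_frequency_features", "pencil_threshold",
           "extract_pencil_features"]


@dataclass(frozen=True)
class FrequencyFeatures:
    peak_magnitude: float   # px
    peak_frequency: float   # Hz
    snr: float              # dimensionless; NaN if no signal bins
    variance: float         # px^2; NaN if no signal bins
    bandwidth: int          # signal bin count
    noise_threshold: float  # px

    def as_dict(self) -> dict:
        return {"peak_magnitude": self.peak_magnitude,
                "peak_frequency": self.peak_frequency,
                "snr": self.snr,
                "variance": self.variance,
                "bandwidth": float(self.bandwidth)}


@dataclass(frozen=True)
class PencilFeatures:
    thickness: float        # stroke px per unit contour arc length
    pressure: float         # mean stroke intensity, 0-255
    final_threshold: float  # intensity cut used for the stroke mask

    def as_dict(self) -> dict:
        return {"thickness": self.thickness, "pressure": self.pressure}


def noise_threshold(spectrum: Spectrum) -> float:
    """Twice the mean spectrum magnitude, rounded to 3 decimals."""
    mags = spectrum.mags
    if mags.size == 0:
        raise ValueError("empty spectrum")
    return round(2.0 * float(np.mean(mags)), 3)


def compute_snr(spectrum: Spectrum, threshold: float) -> float:
    """Mean signal power / mean noise power - 1.

    Bins strictly above ``threshold`` are signal.  Returns NaN when no bin
    qualifies as signal, and +inf when the noise power is zero.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mags = spectrum.mags
    signal = mags[mags > threshold]
    noise = mags[mags <= threshold]
    if signal.size == 0:
        return float("nan")
    signal_power = float(np.sum(signal ** 2)) / signal.size
    if noise.size == 0 or float(np.sum(noise ** 2)) == 0.0:
        return float("inf")
    noise_power = float(np.sum(noise ** 2)) / noise.size
    return signal_power / noise_power - 1.0


def extract_frequency_features(spectrum: Spectrum) -> FrequencyFeatures:
    """All five frequency features of one deviation spectrum."""
    mags = spectrum.mags
    if mags.size == 0:
        raise ValueError("empty spectrum")
    peak_idx = int(np.argmax(mags))  # first occurrence = lowest frequency
    thr = noise_threshold(spectrum)
    signal = mags[mags > thr]
    bandwidth = int(signal.size)
    if bandwidth == 0:
        variance = float("nan")
    else:
        variance = float(np.var(signal))  # population variance
    return FrequencyFeatures(
        peak_magnitude=float(mags[peak_idx]),
        peak_frequency=float(spectrum.freqs[peak_idx]),
        snr=compute_snr(spectrum, thr),
        variance=variance,
        bandwidth=bandwidth,
        noise_threshold=thr,
    )


def pencil_threshold(image: np.ndarray) -> float:
    """Refined global intensity threshold for pencil pixels.

    The initial threshold is the image mean; the margin to white
    (255 - mean) is subtracted from it, giving T = 2*mean - 255, clamped
    to [0, 255].
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    mean = float(img.mean())
    return float(np.clip(2.0 * mean - 255.0, 0.0, 255.0))


def _contour_arc_length(mask: np.ndarray, include_holes: bool = True
                        ) -> float:
    """Summed arc length of the stroke-mask boundaries (sub-pixel)."""
    total = 0.0
    for rc in find_contours(mask.astype(float), 0.5):
        if len(rc) < 2:
            continue
        if not include_holes:
            # hole boundaries enclose background; orientation distinguishes
            x, y = rc[:, 1], rc[:, 0]
            signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
            if signed < 0:
                continue
        total += float(np.sum(np.hypot(*np.diff(rc, axis=0).T)))
    return total


def extract_pencil_features(image: np.ndarray,
                            include_holes: bool = True) -> PencilFeatures:
    """Thickness and pressure of the pencil strokes in a grayscale image.

    Both features are NaN when the stroke mask is empty (blank page) or the
    mask has no measurable boundary; NaN rows are dropped later rather than
    raising here.

    Note on units: the arc length in the denominator is the perimeter of
    the stroke boundaries, roughly twice the drawn path length for a
    ribbon-like stroke, so thickness is a consistent relative measure of
    stroke width rather than the literal width in px.
    """
    img = np.asarray(image, dtype=float)
    thr = pencil_threshold(img)
    mask = img < thr  # strictly below the final threshold
    if not mask.any():
        return PencilFeatures(float("nan"), float("nan"), thr)
    pressure = float(img[mask].mean())
    length = _contour_arc_length(mask, include_holes=include_holes)
    if length <= 0.0:
        return PencilFeatures(float("nan"), float("nan"), thr)
    thickness = float(mask.sum()) / length
    return PencilFeatures(thickness=thickness, pressure=pressure,
                          final_threshold=thr)
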