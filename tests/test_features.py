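"""Frequency features (vs a naive loop oracle) and pencil features."""

import math

import numpy as np
import pytest

from spiraltremor import (Spectrum, compute_snr, extract_frequency_features,
                          extract_pencil_features, noise_threshold,
                          pencil_threshold)


def spectrum_of(mags, fs=10.0):
    mags = np.asarray(mags, float)
    n = 2 * len(mags)
    freqs = np.arange(len(mags)) * fs / n
    return Spectrum(freqs=freqs, mags=mags, n_signal=n)


# ---------------------------------------------------------------- oracle --

from _oracles import naive_features  # noqa: E402


def assert_same(a, b):
    if isinstance(a, float) and math.isnan(a):
        assert isinstance(b, float) and math.isnan(b)
    elif isinstance(a, float) and math.isinf(a):
        assert a == b
    else:
        assert b == pytest.approx(a, rel=1e-12, abs=1e-15)


# ----------------------------------------------------------------- tests --

def test_noise_threshold_hand_cases():
    assert noise_threshold(spectrum_of([1, 1, 10, 1, 1])) == 5.6
    assert noise_threshold(spectrum_of([0, 0, 0])) == 0.0
    assert noise_threshold(spectrum_of([0.3333, 0.3334])) == 0.667


def test_snr_hand_case():
    spec = spectrum_of([1, 1, 10, 1, 1])
    assert compute_snr(spec, 5.6) == pytest.approx(99.0)


def test_snr_degenerate_cases():
    flat = spectrum_of([2.0, 2.0, 2.0, 2.0])
    assert math.isnan(compute_snr(flat, noise_threshold(flat)))
    zero_noise = spectrum_of([0.0, 0.0, 4.0, 0.0])
    assert compute_snr(zero_noise, 2.0) == float("inf")


def test_feature_bundle_hand_cases():
    f = extract_frequency_features(spectrum_of([1, 1, 10, 1, 1], fs=10.0))
    assert (f.peak_magnitude, f.bandwidth, f.variance) == (10.0, 1, 0.0)
    assert f.peak_frequency == pytest.approx(2.0)  # bin 2 of 0,1,2,3,4 Hz
    assert f.noise_threshold == 5.6
    assert f.snr == pytest.approx(99.0)

    g = extract_frequency_features(
        Spectrum(freqs=np.arange(5.0), mags=np.array([0, 8, 0, 6, 0.0]),
                 n_signal=10))
    assert g.noise_threshold == 5.6
    assert g.bandwidth == 2
    assert g.variance == pytest.approx(1.0)   # population variance of {8,6}
    assert g.peak_frequency == 1.0

    flat = extract_frequency_features(spectrum_of([3.0] * 8))
    assert flat.bandwidth == 0
    assert math.isnan(flat.variance) and math.isnan(flat.snr)


def test_peak_tie_breaks_to_lowest_frequency():
    f = extract_frequency_features(spectrum_of([1, 7, 3, 7, 1]))
    assert f.peak_frequency == pytest.approx(1.0 * 10.0 / 10.0)


def test_features_match_naive_oracle_on_random_spectra():
    # dyadic-rational magnitudes: every partial sum is exact in binary
    # floating point, so oracle and implementation see identical means and
    # thresholds regardless of summation order
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(5, 201))
        kind = rng.integers(0, 3)
        if kind == 0:
            mags = rng.integers(0, 2048, n) / 1024.0
        elif kind == 1:
            mags = rng.integers(0, 1024, n) / 1024.0
            mags[rng.integers(0, n)] += rng.integers(5120, 51200) / 1024.0
        else:
            mags = rng.integers(0, 8, n) / 4.0  # many ties
        freqs = np.arange(n) * 0.1
        ours = extract_frequency_features(
            Spectrum(freqs=freqs, mags=mags, n_signal=2 * n))
        ref = naive_features(freqs.tolist(), mags.tolist())
        assert ours.bandwidth == ref["bandwidth"]
        for key in ("peak_magnitude", "peak_frequency", "snr", "variance",
                    "noise_threshold"):
            assert_same(ref[key], getattr(ours, key))


def test_scale_covariance():
    rng = np.random.default_rng(7)
    mags = rng.exponential(1.0, 60)
    mags[13] += 20.0
    base = extract_frequency_features(spectrum_of(mags))
    for c in (2.0, 10.0):
        scaled = extract_frequency_features(spectrum_of(c * mags))
        assert scaled.peak_magnitude == pytest.approx(c * base.peak_magnitude)
        assert scaled.peak_frequency == base.peak_frequency
        assert scaled.bandwidth == base.bandwidth
        assert scaled.variance == pytest.approx(c ** 2 * base.variance,
                                                rel=1e-9)
        assert scaled.snr == pytest.approx(base.snr, rel=1e-6)
        assert scaled.noise_threshold == pytest.approx(
            c * base.noise_threshold, abs=2e-3 * max(c, 1))


# ------------------------------------------------------------- pencil ----

def test_pencil_threshold_formula():
    img240 = np.full((10, 10), 240.0)
    assert pencil_threshold(img240) == 225.0       # 240 - (255-240)
    assert pencil_threshold(np.full((4, 4), 255.0)) == 255.0
    assert pencil_threshold(np.full((4, 4), 100.0)) == 0.0  # clamped


def test_pressure_of_uniform_strokes():
    img = np.full((40, 40), 255, np.uint8)
    img[10:13, 5:35] = 120
    feats = extract_pencil_features(img)
    assert feats.pressure == pytest.approx(120.0)


def test_ribbon_thickness_against_perimeter():
    """A 100x3 ribbon has 300 stroke px over a ~206 px closed boundary."""
    img = np.full((20, 120), 255, np.uint8)
    img[8:11, 10:110] = 120
    feats = extract_pencil_features(img)
    # boundary of a 100x3 pixel block: between the inner (2*(99+2)=202)
    # and outer (2*(101+4)=210) rectangle perimeters
    assert 300 / 210 < feats.thickness < 300 / 202
    assert feats.thickness == pytest.approx(1.46, abs=0.05)


def test_blank_page_gives_nan_features():
    feats = extract_pencil_features(np.full((50, 50), 255, np.uint8))
    assert math.isnan(feats.thickness) and math.isnan(feats.pressure)


def test_pressure_shifts_exactly_with_stroke_darkening():
    img = np.full((40, 40), 255, np.uint8)
    img[10:13, 5:35] = 120
    darker = img.copy()
    darker[darker == 120] = 110
    a = extract_pencil_features(img)
    b = extract_pencil_features(darker)
    assert a.pressure - b.pressure == pytest.approx(10.0)


def test_thickness_monotone_in_stroke_width():
    from spiraltremor import SpiralSpec, render_spiral

    thin_img = render_spiral(SpiralSpec(stroke_width=2, seed=5))
    wide_img = render_spiral(SpiralSpec(stroke_width=4, seed=5))
    t2 = extract_pencil_features(thin_img).thickness
    t4 = extract_pencil_features(wide_img).thickness
    assert t4 > t2
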