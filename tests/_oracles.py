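"""Independent brute-force oracles shared by the test modules."""


def naive_features(freqs, mags):
    """Loop-based re-implementation of the five frequency-feature
    definitions (peak, SNR with 2x-mean threshold, variance, bandwidth)."""
    thr = round(2.0 * (sum(mags) / len(mags)), 3)
    peak_i, peak = 0, mags[0]
    for i, m in enumerate(mags):
        if m > peak:
            peak_i, peak = i, m
    signal = [m for m in mags if m > thr]
    noise = [m for m in mags if m <= thr]
    if not signal:
        snr = float("nan")
        var = float("nan")
    else:
        sig_p = sum(m * m for m in signal) / len(signal)
        noise_sq = sum(m * m for m in noise)
        if not noise or noise_sq == 0.0:
            snr = float("inf")
        else:
            snr = sig_p / (noise_sq / len(noise)) - 1.0
        mean = sum(signal) / len(signal)
        var = sum((m - mean) ** 2 for m in signal) / len(signal)
    return {"peak_magnitude": peak, "peak_frequency": freqs[peak_i],
            "snr": snr, "variance": var, "bandwidth": len(signal),
            "noise_threshold": thr}
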