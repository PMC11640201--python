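"""Reference experiments on synthetic cohorts.

Each function generates its own seeded synthetic drawings, runs the full
pipeline, and reports summary quantities.  They are what the acceptance
script and the validation suite execute; problem sizes (cohort of 50+50,
default 4 px/mm spiral scale, 5 replicate seeds) are the package's standard
study conditions.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from sklearn.model_selection import train_test_split

from .classify import evaluate, train_grid_search
from .dataset import FeatureTable, build_feature_table, clean_table
from .pipeline import (PipelineConfig, image_frequency_features,
                       spiral_trace)
from .simulate import SpiralSpec, make_labeled_set, render_spiral
from .spectrum import deviation_signal, fit_lobf, to_spectrum
from .features import extract_frequency_features

__all__ = ["tremor_recovery", "snr_vs_amplitude", "clean_spiral_null",
           "classification_experiment"]

#: intensity jitter (grayscale std-dev) used for single-spiral experiments;
#: mid-range of the cohort generator's jitter band.
EXPERIMENT_JITTER = 6.0


def tremor_recovery(seed: int = 0, freqs=(3.0, 4.0, 5.0, 6.0),
                    amps=(3.0, 6.0), n_cases: int = 20) -> dict:
    """Recover injected tremor frequencies through the full pipeline.

    Renders ``n_cases`` spirals cycling through the (frequency, amplitude)
    grid with distinct render seeds, and counts how often the pipeline's
    peak frequency lands within one frequency-bin width (fs/n = 1/duration)
    of the injected ground truth.
    """
    combos = list(product(freqs, amps))
    hits, details = 0, []
    for i in range(n_cases):
        f, a = combos[i % len(combos)]
        spec = SpiralSpec(tremor_amplitude=a, tremor_frequency=f,
                          intensity_jitter=EXPERIMENT_JITTER,
                          seed=seed * 1000 + i)
        feats = image_frequency_features(render_spiral(spec))
        bin_width = 1.0 / spec.draw_duration
        hit = abs(feats.peak_frequency - f) <= bin_width + 1e-9
        hits += hit
        details.append({"f": f, "amplitude": a,
                        "peak_frequency": feats.peak_frequency, "hit": hit})
    return {"n_cases": n_cases, "hits": hits, "rate": hits / n_cases,
            "details": details}


def snr_vs_amplitude(seed: int = 0, amplitudes=(0.0, 2.0, 4.0, 8.0),
                     n_seeds: int = 5, frequency: float = 5.0) -> dict:
    """Seed-averaged pipeline SNR for increasing tremor amplitude."""
    means = {}
    for a in amplitudes:
        snrs = []
        for k in range(n_seeds):
            spec = SpiralSpec(tremor_amplitude=a, tremor_frequency=frequency,
                              intensity_jitter=EXPERIMENT_JITTER,
                              seed=seed * 1000 + k)
            snrs.append(image_frequency_features(render_spiral(spec)).snr)
        means[a] = float(np.mean(snrs))
    return means


def clean_spiral_null(seed: int = 0) -> dict:
    """Deviation statistics of a tremor-free rendered spiral."""
    trace = spiral_trace(render_spiral(SpiralSpec(seed=seed)))
    dev = deviation_signal(trace, fit_lobf(trace))
    feats = extract_frequency_features(to_spectrum(dev))
    return {"deviation_rms": float(np.sqrt(np.mean(dev.amplitudes ** 2))),
            "bandwidth": feats.bandwidth,
            "peak_magnitude": feats.peak_magnitude,
            "n_points": trace.n_points}


def _subset(table: FeatureTable, feature_set: str) -> FeatureTable:
    from .pipeline import FEATURE_SETS

    cols = ["id", "label"] + FEATURE_SETS[feature_set]
    return FeatureTable(table.df[cols].copy(), feature_set=feature_set)


def classification_experiment(seed: int = 0, n_per_class: int = 50,
                              n_seeds: int = 5, algorithm: str = "RF",
                              test_fraction: float = 0.2) -> dict:
    """Healthy-vs-PD classification on synthetic cohorts.

    For each replicate: generate ``n_per_class`` drawings per class, split
    80/20 stratified, extract all seven features once, and train/evaluate
    the classifier on the F, P and FP feature subsets.  Returns per-set
    per-replicate test accuracies and their means.
    """
    config = PipelineConfig()
    accs = {fs: [] for fs in ("F", "P", "FP")}
    for k in range(n_seeds):
        rep_seed = seed * 1000 + k
        cohort = make_labeled_set(n_per_class, n_per_class, seed=rep_seed)
        idx = np.arange(len(cohort))
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, stratify=cohort.labels,
            random_state=rep_seed % (2**31 - 1))
        full = build_feature_table(cohort.images, cohort.labels, "FP",
                                   config=config)
        train_full = FeatureTable(full.df.iloc[train_idx].copy(), "FP")
        test_full = FeatureTable(full.df.iloc[test_idx].copy(), "FP")
        for fs in ("F", "P", "FP"):
            train_tab = clean_table(_subset(train_full, fs))
            test_tab = clean_table(_subset(test_full, fs))
            model = train_grid_search(train_tab, algorithm=algorithm,
                                      seed=rep_seed % (2**31 - 1))
            accs[fs].append(evaluate(model, test_tab).accuracy)
    return {"per_seed": accs,
            "mean": {fs: float(np.mean(v)) for fs, v in accs.items()}}
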