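"""End-to-end per-image pipelines composing the processing stages."""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np

from .exceptions import SpiralError
from .features import (FrequencyFeatures, PencilFeatures,
                       extract_frequency_features, extract_pencil_features)
from .preprocess import binarize_spiral, largest_contour, thin
from .spectrum import LobfConfig, deviation_signal, fit_lobf, to_spectrum
from .unwrap import PolarTrace, find_center, refine_center, unwrap_spiral

__all__ = ["PipelineConfig", "spiral_trace", "image_frequency_features",
           "image_pencil_features", "extract_record", "write_debug_artifacts",
           "FREQ_FEATURES", "PENCIL_FEATURES", "FEATURE_SETS"]

FREQ_FEATURES = ["peak_magnitude", "peak_frequency", "snr", "variance",
                 "bandwidth"]
PENCIL_FEATURES = ["thickness", "pressure"]
FEATURE_SETS = {"F": FREQ_FEATURES,
                "P": PENCIL_FEATURES,
                "FP": FREQ_FEATURES + PENCIL_FEATURES}


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the image-to-features pipeline (defaults used throughout)."""

    blur_kernel: int = 5
    block_size: int = 11
    offset_c: float = 2.0
    smoothing_scale: float = 10.0   # N in s = n_points * N
    draw_duration: float = 10.0     # seconds; defines fs = n / duration
    include_holes: bool = True      # count hole boundaries in arc length
    refine_center: bool = True      # sub-pixel center refinement


def spiral_trace(image: np.ndarray,
                 config: PipelineConfig = PipelineConfig()) -> PolarTrace:
    """Grayscale drawing -> unwrapped angle-distance trace."""
    mask = binarize_spiral(image, blur_kernel=config.blur_kernel,
                           block_size=config.block_size,
                           offset_c=config.offset_c)
    skeleton = thin(mask)
    center = find_center(largest_contour(mask))
    if config.refine_center:
        center = refine_center(skeleton, center)
    return unwrap_spiral(skeleton, center)


def image_frequency_features(image: np.ndarray,
                             config: PipelineConfig = PipelineConfig()
                             ) -> FrequencyFeatures:
    """Grayscale drawing -> the five frequency-domain tremor features."""
    trace = spiral_trace(image, config)
    lobf = fit_lobf(trace, LobfConfig(config.smoothing_scale))
    dev = deviation_signal(trace, lobf, draw_duration=config.draw_duration)
    return extract_frequency_features(to_spectrum(dev))


def image_pencil_features(image: np.ndarray,
                          config: PipelineConfig = PipelineConfig()
                          ) -> PencilFeatures:
    """Grayscale drawing -> pencil thickness and pressure."""
    return extract_pencil_features(image, include_holes=config.include_holes)


def write_debug_artifacts(image: np.ndarray, out_dir,
                          config: PipelineConfig = PipelineConfig()) -> dict:
    """Dump intermediate pipeline stages for visual inspection.

    Writes ``mask.png`` and ``skeleton.png``, the unwrapped trace as
    ``trace.csv`` (angle_rad, distance_px) and the deviation spectrum as
    ``spectrum.csv`` (freq_hz, magnitude).  Returns the written paths.
    """
    from pathlib import Path

    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask = binarize_spiral(image, blur_kernel=config.blur_kernel,
                           block_size=config.block_size,
                           offset_c=config.offset_c)
    skeleton = thin(mask)
    paths = {}
    for name, arr in (("mask", mask), ("skeleton", skeleton)):
        p = out_dir / f"{name}.png"
        Image.fromarray((arr.astype(np.uint8)) * 255).save(p)
        paths[name] = p
    trace = spiral_trace(image, config)
    p = out_dir / "trace.csv"
    np.savetxt(p, np.column_stack([trace.angles, trace.distances]),
               delimiter=",", header="angle_rad,distance_px", comments="")
    paths["trace"] = p
    lobf = fit_lobf(trace, LobfConfig(config.smoothing_scale))
    spec = to_spectrum(deviation_signal(trace, lobf,
                                        draw_duration=config.draw_duration))
    p = out_dir / "spectrum.csv"
    np.savetxt(p, np.column_stack([spec.freqs, spec.mags]),
               delimiter=",", header="freq_hz,magnitude", comments="")
    paths["spectrum"] = p
    return paths


def extract_record(image: np.ndarray, feature_set: str = "FP",
                   config: PipelineConfig = PipelineConfig()) -> dict:
    """One feature row for an image; failures yield NaN values, not errors.

    Unusable drawings (self-intersecting skeleton, blank page, ...) produce
    NaN in the affected columns and are removed later by table cleaning.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    row = {}
    if feature_set in ("F", "FP"):
        try:
            row.update(image_frequency_features(image, config).as_dict())
        except (SpiralError, ValueError):
            row.update({k: nan for k in FREQ_FEATURES})
    if feature_set in ("P", "FP"):
        try:
            row.update(image_pencil_features(image, config).as_dict())
        except (SpiralError, ValueError):
            row.update({k: nan for k in PENCIL_FEATURES})
    return row
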