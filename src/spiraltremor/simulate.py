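"""Synthetic Archimedean-spiral drawings with known tremor ground truth.

The generator emulates pencil-on-paper spiral drawings: a dark stroke of
finite width following r = a*theta (the guided drawing used in spiral tests
is 4.5 revolutions with a 75 mm maximum radius, drawn clockwise), plus an
optional radial tremor term

    r(theta) = a*theta + A * sin(2*pi*f * t(theta))

where the drawing time t advances uniformly with arc length from 0 to
``draw_duration`` (default 10 s, the nominal time a healthy subject takes to
draw the spiral).  Because downstream analysis assigns each traced pixel a
uniform time step, a tremor injected at f Hz reappears at f Hz in the
deviation spectrum — this is the ground truth the test-suite checks against.

Physical scale: the 75 mm maximum radius is mapped to pixels through a
configurable ``px_per_mm`` (default 4), giving the default radial growth
rate ``a`` of about 10.6 px/rad.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.ndimage import distance_transform_edt

from .exceptions import CanvasOverflowError

__all__ = [
    "SpiralSpec",
    "SpecRanges",
    "LabeledImageSet",
    "HEALTHY_RANGES",
    "PD_RANGES",
    "growth_rate",
    "render_spiral",
    "make_labeled_set",
]

MAX_RADIUS_MM = 75.0
DEFAULT_REVOLUTIONS = 4.5
DEFAULT_PX_PER_MM = 4.0
BACKGROUND = 255


def growth_rate(max_radius_mm: float = MAX_RADIUS_MM,
                revolutions: float = DEFAULT_REVOLUTIONS,
                px_per_mm: float = DEFAULT_PX_PER_MM) -> float:
    """Radial growth rate a (px/rad) for a spiral of given physical size."""
    return max_radius_mm * px_per_mm / (2.0 * np.pi * revolutions)


@dataclass(frozen=True)
class SpiralSpec:
    """Generative parameters of one synthetic spiral drawing.

    Parameters
    ----------
    a : radial growth rate in px/rad.
    revolutions : number of turns of the guide spiral.
    tremor_amplitude : radial tremor amplitude A in px.
    tremor_frequency : tremor frequency f in Hz.
    draw_duration : nominal drawing time in seconds.
    stroke_width : pencil stroke width in px.
    stroke_intensity : grayscale value of the stroke (dark, 0-255).
    intensity_jitter : per-pixel Gaussian std-dev of stroke intensity.
    image_size : side of the square canvas in px.
    direction : 'clockwise' (as drawn in the guided test) or
        'counterclockwise', in screen orientation (y axis pointing down).
    seed : RNG seed for the intensity jitter.
    """

    a: float = growth_rate()
    revolutions: float = DEFAULT_REVOLUTIONS
    tremor_amplitude: float = 0.0
    tremor_frequency: float = 5.0
    draw_duration: float = 10.0
    stroke_width: int = 3
    stroke_intensity: int = 90
    intensity_jitter: float = 0.0
    image_size: int = 672
    direction: str = "clockwise"
    seed: int = 0

    def validate(self) -> None:
        if self.a <= 0:
            raise ValueError("growth rate a must be > 0")
        if self.revolutions <= 0:
            raise ValueError("revolutions must be > 0")
        if self.tremor_amplitude < 0 or self.tremor_frequency < 0:
            raise ValueError("tremor amplitude and frequency must be >= 0")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.stroke_intensity + 3.0 * self.intensity_jitter >= BACKGROUND:
            raise ValueError("stroke intensity too close to background; "
                             "strokes would not be separable")
        reach = (self.a * 2.0 * np.pi * self.revolutions
                 + self.tremor_amplitude + self.stroke_width)
        if reach >= self.image_size / 2.0:
            raise CanvasOverflowError(
                f"spiral exceeds canvas: reach {reach:.1f} px vs "
                f"half-frame {self.image_size / 2.0:.1f} px")


def _path_coordinates(spec: SpiralSpec, n_samples: int = 20001):
    """Dense (x, y) samples of the spiral curve in image coordinates.

    Sampling is dense enough that adjacent samples are well under 1 px
    apart, so marking the nearest pixel of every sample yields a connected
    8-path.  Time is assigned proportionally to arc length of the tremor-free
    guide, modelling a constant drawing speed.
    """
    theta = np.linspace(0.0, 2.0 * np.pi * spec.revolutions, n_samples)
    r_base = spec.a * theta
    # arc length of the guide spiral -> uniform drawing speed along the path
    ds = np.hypot(np.diff(r_base), r_base[:-1] * np.diff(theta))
    s = np.concatenate([[0.0], np.cumsum(ds)])
    t = spec.draw_duration * s / s[-1]
    r = r_base + spec.tremor_amplitude * np.sin(
        2.0 * np.pi * spec.tremor_frequency * t)
    sign = 1.0 if spec.direction == "clockwise" else -1.0
    c = (spec.image_size - 1) / 2.0
    x = c + r * np.cos(theta)
    y = c + sign * r * np.sin(theta)  # y grows downward in image coords
    return x, y


def render_spiral(spec: SpiralSpec, return_mask: bool = False):
    """Rasterize a spiral drawing.

    Returns a uint8 ``image_size x image_size`` array, background 255,
    stroke pixels at ``stroke_intensity`` plus per-pixel jitter.  With
    ``return_mask=True`` also returns the boolean stroke mask the renderer
    painted, which downstream tests use as pixel-level ground truth.

    Identical spec (including seed) gives a bit-identical raster.
    """
    spec.validate()
    x, y = _path_coordinates(spec)
    n = spec.image_size
    path = np.zeros((n, n), dtype=bool)
    rows = np.clip(np.rint(y).astype(int), 0, n - 1)
    cols = np.clip(np.rint(x).astype(int), 0, n - 1)
    path[rows, cols] = True
    if spec.stroke_width > 1:
        # thicken by Euclidean distance from the 1-px path; no anti-aliasing
        dist = distance_transform_edt(~path)
        mask = dist < spec.stroke_width / 2.0
    else:
        mask = path
    image = np.full((n, n), BACKGROUND, dtype=np.uint8)
    rng = np.random.default_rng(spec.seed)
    values = np.full(int(mask.sum()), float(spec.stroke_intensity))
    if spec.intensity_jitter > 0:
        values = values + rng.normal(0.0, spec.intensity_jitter, values.size)
    image[mask] = np.clip(np.rint(values), 0, 255).astype(np.uint8)
    if return_mask:
        return image, mask
    return image


@dataclass(frozen=True)
class SpecRanges:
    """Uniform sampling ranges for each :class:`SpiralSpec` field.

    Scalar fields are sampled uniformly from ``(low, high)``;
    ``stroke_width`` is sampled as an integer from its inclusive range.
    """

    a: tuple = (9.5, 11.5)
    tremor_amplitude: tuple = (0.0, 1.0)
    tremor_frequency: tuple = (3.0, 7.0)
    stroke_width: tuple = (3, 5)
    stroke_intensity: tuple = (70, 140)
    intensity_jitter: tuple = (4.0, 10.0)

    def sample(self, rng: np.random.Generator, **fixed) -> SpiralSpec:
        def u(lo_hi):
            lo, hi = lo_hi
            return float(rng.uniform(lo, hi))

        return SpiralSpec(
            a=u(self.a),
            tremor_amplitude=u(self.tremor_amplitude),
            tremor_frequency=u(self.tremor_frequency),
            stroke_width=int(rng.integers(self.stroke_width[0],
                                          self.stroke_width[1] + 1)),
            stroke_intensity=int(round(u(self.stroke_intensity))),
            intensity_jitter=u(self.intensity_jitter),
            seed=int(rng.integers(0, 2**31 - 1)),
            **fixed,
        )


#: Control drawings: essentially tremor-free (sub-pixel radial wobble).
HEALTHY_RANGES = SpecRanges()

#: Parkinsonian drawings: 4-6 Hz rest/action-tremor band, visible amplitude,
#: on average darker (heavier pressure) and slightly thicker strokes.
PD_RANGES = SpecRanges(
    tremor_amplitude=(2.5, 6.0),
    tremor_frequency=(4.0, 6.0),
    stroke_width=(3, 7),
    stroke_intensity=(50, 110),
)


@dataclass
class LabeledImageSet:
    """Images + labels + the specs that generated them."""

    images: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    manifest: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


def make_labeled_set(n_healthy: int,
                     n_pd: int,
                     healthy_ranges: SpecRanges = HEALTHY_RANGES,
                     pd_ranges: SpecRanges = PD_RANGES,
                     seed: int = 0,
                     **spec_overrides) -> LabeledImageSet:
    """Generate a labeled cohort of synthetic spiral drawings.

    ``spec_overrides`` (e.g. ``image_size``) are applied to every sampled
    spec.  Reproducible: the same arguments give the same manifest and
    bit-identical images.
    """
    if n_healthy < 0 or n_pd < 0:
        raise ValueError("cohort sizes must be >= 0")
    if healthy_ranges is None or pd_ranges is None:
        raise ValueError("spec ranges must be provided")
    rng = np.random.default_rng(seed)
    out = LabeledImageSet()
    plan = [("healthy", healthy_ranges)] * n_healthy
    plan += [("parkinson", pd_ranges)] * n_pd
    for label, ranges in plan:
        spec = ranges.sample(rng, **spec_overrides)
        out.images.append(render_spiral(spec))
        out.labels.append(label)
        out.manifest.append(spec)
    return out


def spec_to_row(spec: SpiralSpec) -> dict:
    """Flatten a spec into a manifest-CSV row."""
    return {f.name: getattr(spec, f.name) for f in fields(SpiralSpec)}


def scaled(spec_ranges: SpecRanges, px_per_mm: float) -> SpecRanges:
    """Rescale the geometric ranges of a cohort to another px/mm.

    Growth rate and tremor amplitude scale with px/mm (they are physical
    lengths); stroke appearance ranges are left unchanged.
    """
    k = px_per_mm / DEFAULT_PX_PER_MM
    return replace(spec_ranges,
                   a=(spec_ranges.a[0] * k, spec_ranges.a[1] * k),
                   tremor_amplitude=(spec_ranges.tremor_amplitude[0] * k,
                                     spec_ranges.tremor_amplitude[1] * k))
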