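"""Unwrap a spiral skeleton into an ordered angle-distance trace.

The thinned spiral is walked pixel-by-pixel from the end nearest its center
outward.  Each visited pixel (x_i, y_i) contributes its Euclidean distance

    d_i = sqrt((x_i - x_c)^2 + (y_i - y_c)^2)

to the center (x_c, y_c), and its polar angle atan2(y_i - y_c, x_i - x_c).
Raw angles are only defined modulo 2*pi; they are cumulatively unwrapped
(successive increments kept in (-pi, pi)) so a multi-revolution spiral gets
a continuous, monotone angle axis, then sign-normalized so reported angles
are non-negative and increasing regardless of drawing direction.

Drawings whose skeleton branches (self-intersections, touching turns) are
rejected with :class:`UnusableSpiralError` rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UnusableSpiralError
from .preprocess import Contour

__all__ = ["Center", "PolarTrace", "find_center", "refine_center",
           "unwrap_spiral"]

# pixels closer to the center than this have no meaningful polar angle
_R_ANGLE_MIN = 2.0

# 8-neighbourhood in cyclic order (used for the branch-count test)
_CYCLE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass(frozen=True)
class Center:
    """Spiral center in pixel coordinates (x = column, y = row).

    ``find_center`` returns integer pixel coordinates; the refined center
    produced by :func:`refine_center` is sub-pixel.
    """

    x: float
    y: float


@dataclass
class PolarTrace:
    """Ordered angle-distance series of the unwrapped spiral."""

    angles: np.ndarray     # radians, continuous across revolutions
    distances: np.ndarray  # px

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.angles.shape != self.distances.shape or self.angles.ndim != 1:
            raise ValueError("angles and distances must be equal-length 1-D")
        if len(self.angles) < 2:
            raise ValueError("a trace needs at least 2 points")
        if (self.distances < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n_points(self) -> int:
        return len(self.angles)


def find_center(contour: Contour) -> Center:
    """Area centroid of the contour polygon, rounded to the nearest pixel."""
    pts = contour.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area6 = 3.0 * np.sum(cross)
    if abs(area6) < 1e-12:
        raise ValueError("degenerate (zero-area) contour has no centroid")
    cx = float(np.sum((x + xn) * cross) / area6)
    cy = float(np.sum((y + yn) * cross) / area6)
    return Center(x=int(round(cx)), y=int(round(cy)))


def _branch_counts(skeleton: np.ndarray) -> np.ndarray:
    """Rutovitz crossing number: 0->1 transitions around each pixel.

    A value >= 3 marks a junction (three or more arms meet); simple path
    pixels score 2 and endpoints score 1.  This is robust to the staircase
    corners a Zhang-Suen skeleton produces, which can have three foreground
    8-neighbours without being true junctions.
    """
    padded = np.pad(skeleton, 1).astype(bool)
    rings = []
    for dr, dc in _CYCLE:
        rings.append(padded[1 + dr:padded.shape[0] - 1 + dr,
                            1 + dc:padded.shape[1] - 1 + dc])
    rings = np.stack(rings)
    nxt = np.roll(rings, -1, axis=0)
    return np.sum(~rings & nxt, axis=0)


def _walk(first, origin, visited, pixel_set):
    """Greedy 8-connected walk starting by stepping from origin to first."""
    path = []
    prev, cur = origin, first
    while True:
        visited.add(cur)
        path.append(cur)
        cands = [(cur[0] + dr, cur[1] + dc) for dr, dc in _CYCLE
                 if (cur[0] + dr, cur[1] + dc) in pixel_set
                 and (cur[0] + dr, cur[1] + dc) not in visited]
        if not cands:
            return path
        if len(cands) == 1:
            prev, cur = cur, cands[0]
            continue
        # staircase cluster: prefer the candidate continuing the current
        # direction of motion (minimal angular discontinuity)
        head = np.arctan2(cur[0] - prev[0], cur[1] - prev[1])
        def turn(c):
            ang = np.arctan2(c[0] - cur[0], c[1] - cur[1])
            return abs((ang - head + np.pi) % (2 * np.pi) - np.pi)
        prev, cur = cur, min(cands, key=turn)


def _traverse(skeleton: np.ndarray, center: Center) -> np.ndarray:
    """Ordered (row, col) path covering the skeleton, or raise."""
    skeleton = np.asarray(skeleton, dtype=bool)
    rows, cols = np.nonzero(skeleton)
    if rows.size < 2:
        raise ValueError("skeleton has fewer than 2 foreground pixels")
    h, w = skeleton.shape
    if not (0 <= center.x < w and 0 <= center.y < h):
        raise ValueError("center lies outside the image")

    branch = _branch_counts(skeleton)
    if np.any(branch[skeleton] >= 3):
        raise UnusableSpiralError(
            "skeleton has junctions (self-intersecting drawing); "
            "image is unusable")

    pixel_set = set(zip(rows.tolist(), cols.tolist()))
    d2 = (rows - center.y) ** 2 + (cols - center.x) ** 2
    start = (int(rows[np.argmin(d2)]), int(cols[np.argmin(d2)]))

    visited = {start}
    neighbours = [(start[0] + dr, start[1] + dc) for dr, dc in _CYCLE
                  if (start[0] + dr, start[1] + dc) in pixel_set]
    if not neighbours:
        raise UnusableSpiralError("start pixel is isolated")
    fwd = _walk(neighbours[0], start, visited, pixel_set)
    path = [start] + fwd
    rest = [n for n in neighbours[1:] if n not in visited]
    if rest:
        back = _walk(rest[0], start, visited, pixel_set)
        path = back[::-1] + path
    if len(path) < len(pixel_set):
        # unreachable pixels: disconnected fragments -> not a single stroke
        missing = len(pixel_set) - len(path)
        if missing > 0.05 * len(pixel_set):
            raise UnusableSpiralError(
                f"{missing} skeleton pixels unreachable from the start; "
                "drawing is fragmented")
    return np.asarray(path, dtype=float)


def refine_center(skeleton: np.ndarray, center: Center,
                  n_iter: int = 3) -> Center:
    """Refine a coarse center estimate to sub-pixel accuracy.

    The area centroid of a spiral contour is biased away from the true
    center by roughly twice the radial growth rate, because a spiral with a
    fractional number of turns (4.5 here) has a lopsided final half-turn.
    A center offset leaves a first-order signature on the unwrapped
    distances: a once-per-revolution component -dx*cos(alpha) - dy*sin(alpha)
    in the raw polar angle alpha.  Each iteration regresses the distances on
    a smooth trend in the continuous angle plus (cos alpha, sin alpha) and
    moves the center by the fitted coefficients.
    """
    path = _traverse(skeleton, center)
    cx, cy = float(center.x), float(center.y)
    for _ in range(n_iter):
        dy = path[:, 0] - cy
        dx = path[:, 1] - cx
        d = np.hypot(dx, dy)
        alpha = np.arctan2(dy, dx)
        theta = np.unwrap(alpha)
        t = (theta - theta[0]) / max(abs(theta[-1] - theta[0]), 1e-9)
        design = np.column_stack([np.ones_like(t), t, t**2, t**3,
                                  np.cos(alpha), np.sin(alpha)])
        coef, *_ = np.linalg.lstsq(design, d, rcond=None)
        cx += coef[4]
        cy += coef[5]
    return Center(x=cx, y=cy)


def unwrap_spiral(skeleton: np.ndarray, center: Center) -> PolarTrace:
    """Traverse the skeleton from the center outward and unwrap it.

    Raises
    ------
    UnusableSpiralError
        If the skeleton has junction pixels (crossing number >= 3), is a
        closed loop, or cannot be covered by a single open walk.
    """
    p = _traverse(skeleton, center)
    dy = p[:, 0] - center.y
    dx = p[:, 1] - center.x
    distances = np.hypot(dx, dy)
    if distances[0] > distances[-1]:  # orient the walk inside-out
        distances = distances[::-1]
        dy, dx = dy[::-1], dx[::-1]
    # Unwrap the per-pixel atan2 angles from the OUTER end inward: branch
    # decisions are then made where the radius is large and the angle
    # well-conditioned, so the near-center pixels (whose polar angle is
    # inherently noisy) cannot derail the whole series.
    alpha = np.arctan2(dy, dx)
    angles = np.unwrap(alpha[::-1])[::-1].copy()
    # report non-negative, (net) increasing angles for either direction
    if angles[-1] < angles[0]:
        angles = -angles
    # A pixel closer to the center than _R_ANGLE_MIN has an essentially
    # undefined polar angle (atan2 of a sub-pixel offset): give the prefix
    # of such pixels angles extrapolated from the local angle-distance
    # trend instead of meaningless atan2 values.
    i0 = int(np.argmax(distances >= _R_ANGLE_MIN))
    if i0 > 0 and distances[i0] >= _R_ANGLE_MIN:
        j = min(i0 + 50, len(angles) - 1)
        dd = distances[j] - distances[i0]
        if dd > 0:
            slope = (angles[j] - angles[i0]) / dd
            angles[:i0] = angles[i0] - (distances[i0]
                                        - distances[:i0]) * slope
    angles = angles - angles.min()
    return PolarTrace(angles=angles, distances=distances)
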