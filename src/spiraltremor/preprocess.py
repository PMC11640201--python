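"""From raw drawing to binary mask, one-pixel skeleton, and largest contour.

Coordinate convention used throughout the package: ``x`` is the column
index, ``y`` the row index, origin at the top-left of the image.  Input
drawings are assumed dark-on-light (pencil on paper); light-on-dark inputs
are rejected rather than silently inverted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.filters import gaussian, threshold_local
from skimage.measure import find_contours
from skimage.morphology import skeletonize

from .exceptions import NoForegroundError

__all__ = ["Contour", "load_gray", "binarize_spiral", "thin",
           "largest_contour"]


@dataclass
class Contour:
    """Closed boundary as an ordered (x, y) = (col, row) point array."""

    points: np.ndarray  # shape (n, 2), float sub-pixel coordinates

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 \
                or len(self.points) < 3:
            raise ValueError("a contour needs at least 3 (x, y) points")

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)


def load_gray(path) -> np.ndarray:
    """Read a PNG/JPEG drawing as a uint8 grayscale array.

    Color images are reduced with the standard luma weighting.
    """
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def _blur_sigma(kernel: int) -> float:
    # sigma implied by a Gaussian kernel of the given odd width
    # (0.3*((k-1)/2 - 1) + 0.8, the usual kernel-to-sigma rule)
    return 0.3 * ((kernel - 1) / 2.0 - 1.0) + 0.8


def binarize_spiral(image: np.ndarray,
                    blur_kernel: int = 5,
                    block_size: int = 11,
                    offset_c: float = 2.0) -> np.ndarray:
    """Gaussian blur + adaptive (local Gaussian-mean) threshold.

    Foreground (True) are pixels darker than their local neighbourhood mean
    minus ``offset_c`` — i.e. the pencil strokes on light paper.

    Raises
    ------
    NoForegroundError
        If no pixel qualifies (blank page) or if the majority of the image
        qualifies (light-on-dark polarity, unsupported).
    """
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError("block_size must be odd and >= 3")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        raise ValueError("binarize_spiral expects a grayscale image; "
                         "use load_gray() for color inputs")
    if img.size == 0:
        raise NoForegroundError("empty image")
    if img.mean() < 127.5:
        raise NoForegroundError(
            "image is mostly dark; input appears light-on-dark, which is "
            "unsupported (drawings must be dark strokes on light paper)")
    blurred = gaussian(img, sigma=_blur_sigma(blur_kernel),
                       preserve_range=True)
    local_mean = threshold_local(blurred, block_size=block_size,
                                 method="gaussian", offset=offset_c)
    mask = blurred < local_mean
    frac = mask.mean()
    if frac == 0.0:
        raise NoForegroundError("no foreground detected")
    if frac > 0.5:
        raise NoForegroundError(
            "foreground covers most of the image; input appears "
            "light-on-dark, which is unsupported")
    return mask


def thin(mask: np.ndarray) -> np.ndarray:
    """Zhang–Suen morphological thinning to a one-pixel-wide skeleton.

    The skeleton is a subset of the mask and the operation is idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot thin an empty mask")
    return skeletonize(mask, method="zhang")


def largest_contour(mask: np.ndarray) -> Contour:
    """Boundary with the largest enclosed area among all mask boundaries."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoForegroundError("mask has no foreground; no contour")
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise NoForegroundError("no contour found")
    best, best_area = None, -1.0
    for rc in contours:
        if len(rc) < 3:
            continue
        c = Contour(rc[:, ::-1])  # (row, col) -> (x, y)
        if c.area > best_area:
            best, best_area = c, c.area
    if best is None or best_area <= 0.0:
        raise NoForegroundError("only degenerate contours found")
    return best
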