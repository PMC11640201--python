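"""Domain-specific error types.

All inherit :class:`ValueError` so callers that do not care about the exact
failure mode can catch one base class.
"""


class SpiralError(ValueError):
    """Base class for spiral-processing failures."""


class CanvasOverflowError(SpiralError):
    """The requested spiral does not fit inside the image frame."""


class NoForegroundError(SpiralError):
    """Binarization found no plausible dark-on-light stroke pixels."""


class UnusableSpiralError(SpiralError):
    """The skeleton cannot be traversed as a single open path.

    Raised for self-intersecting or branching drawings; such images are
    excluded from analysis rather than heuristically repaired.
    """


class EmptyTableError(SpiralError):
    """Every feature row was dropped during NaN cleaning."""
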