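"""Exception hierarchy for the ctcmorph pipeline.

Per-tile quality failures are *not* exceptions: they become QC flags and
rejection reasons so a gallery run never dies mid-batch. Exceptions are
reserved for malformed inputs, bad configuration and degenerate calls.
"""


class CtcMorphError(Exception):
    """Base class for all ctcmorph errors."""


class FormatError(CtcMorphError):
    """An image file violates the tile format contract (e.g. non-square)."""


class ManifestError(CtcMorphError):
    """A gallery manifest is malformed (duplicate ids, bad channel roles)."""


class ConfigError(CtcMorphError):
    """Invalid or inconsistent pipeline configuration."""


class CalibrationError(CtcMorphError):
    """Invalid inputs to the pixel-to-micrometer calibration."""


class DegenerateImageError(CtcMorphError):
    """An image has no two intensity classes (constant input)."""


class ContourError(CtcMorphError):
    """No usable contour could be traced from a mask."""


class EllipseFitError(CtcMorphError):
    """The direct least-squares conic fit failed or is not an ellipse."""


class InvalidGeometryError(CtcMorphError):
    """Areas violate geometric preconditions (e.g. nucleus >= cell)."""
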