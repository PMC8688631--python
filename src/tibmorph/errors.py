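"""Exception hierarchy for tibmorph.

All data/geometry failures derive from :class:`TibmorphError` so callers (and
the CLI) can distinguish bad input from programming errors.
"""


class TibmorphError(Exception):
    """Base class for all tibmorph data and geometry errors."""


class STLParseError(TibmorphError):
    """Malformed STL file (message names the offending byte offset)."""


class GeometryError(TibmorphError):
    """Degenerate 3D construction (coincident landmarks, parallel axes...)."""


class DegenerateAxisError(GeometryError):
    """Mechanical-axis landmarks coincide (distance <= 1 mm)."""


class EmptySliceError(GeometryError):
    """The resection plane does not intersect the mesh."""


class OpenContourError(GeometryError):
    """Slice segments cannot be chained into a closed loop within tolerance."""


class ContourError(TibmorphError):
    """A measurement on a planar contour is ill-defined."""


class AmbiguousSectionError(ContourError):
    """A section line crosses the contour a number of times != 2."""


class DegenerateContourError(ContourError):
    """A half-contour (or the contour itself) is empty or degenerate."""


class InsufficientArcError(ContourError):
    """Fewer than 3 points selected for an anterior-radius circle fit."""


class NoCircleError(ContourError):
    """Circle fit requested on collinear (or < 3) points."""


class GeneratorInfeasibleError(TibmorphError):
    """A ParameterVector cannot be realized as a simple contour."""


class SpecInfeasibleError(TibmorphError):
    """Population sampling rejected too many consecutive draws."""


class UndefinedStatisticError(TibmorphError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
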