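"""Exception hierarchy.

All package errors derive from :class:`LeafGasketError` so callers (and the
CLI) can catch one base class and emit a single-line diagnostic.
"""


class LeafGasketError(ValueError):
    """Base class for all errors raised by this package."""


class InvalidGasketError(LeafGasketError):
    """Gasket specification is unusable (e.g. non-positive area)."""


class InvalidWidthError(LeafGasketError):
    """Leaf width (or half-width) outside its admissible range."""


class InvalidAngleError(LeafGasketError):
    """Central angle outside [0, 360] degrees."""


class InvalidAreaError(LeafGasketError):
    """A leaf area that must be positive (and at most the gasket area) is not."""


class OversizedAreaError(InvalidAreaError):
    """Measured leaf area exceeds the instrument's assumed area."""


class UndefinedIWUEError(LeafGasketError):
    """Intrinsic water-use efficiency is undefined (stomatal conductance <= 0)."""


class ScaleNotFoundError(LeafGasketError):
    """No printed scale bar could be detected in the image."""


class CircleNotFoundError(LeafGasketError):
    """No gasket-impression circle could be detected in the image."""


class AmbiguousContrastError(LeafGasketError):
    """Segmentation foreground fills essentially the whole aperture yet the
    histogram is bimodal -- the leaf/background contrast cannot be trusted."""


class SchemaError(LeafGasketError):
    """An instrument log is missing mandatory columns."""


class JoinError(LeafGasketError):
    """Log rows and area annotations could not be matched one-to-one."""


class InvalidReferenceError(LeafGasketError):
    """Agreement statistic referenced to a non-positive area."""


class DegenerateRegressionError(LeafGasketError):
    """Through-origin regression with an all-zero predictor."""


class ParameterError(LeafGasketError):
    """Invalid synthetic-generator parameters."""


class LayoutError(LeafGasketError):
    """Rendered scene elements overlap (leaf or circle collides with the bar)."""
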