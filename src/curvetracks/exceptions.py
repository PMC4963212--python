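"""Exception hierarchy.

All errors raised by this package derive from :class:`CurveTracksError` so
callers can catch everything package-specific with one clause.
"""


class CurveTracksError(Exception):
    """Base class for all curvetracks errors."""


class TrackFormatError(CurveTracksError, ValueError):
    """Input table is malformed (missing column, duplicate key, bad dtype)."""


class EmptyInputError(CurveTracksError, ValueError):
    """An operation received no usable data."""


class ParameterError(CurveTracksError, ValueError):
    """A parameter is outside its valid domain."""


class DegenerateFitError(CurveTracksError, ValueError):
    """A geometric fit is degenerate (collinear points, non-ellipse conic, ...)."""


class SliceCoverageError(CurveTracksError, ValueError):
    """A data slab holds too few points to fit its cross-section."""


class DisconnectedGraphError(CurveTracksError, ValueError):
    """The neighborhood graph is disconnected; carries component sizes."""

    def __init__(self, component_sizes):
        self.component_sizes = sorted(component_sizes, reverse=True)
        super().__init__(
            "neighborhood graph is disconnected "
            f"(component sizes: {self.component_sizes}); "
            "increase k or the bandwidth, or supply denser data"
        )


class DimensionalityError(CurveTracksError, ValueError):
    """The embedding collapsed to (effectively) one dimension.

    This is the known failure mode of locally linear embedding on very
    narrow surfaces sampled sparsely: the algorithm reads the cloud as a
    1D filament and the second coordinate carries no independent spatial
    extent.
    """


class MetricQualityError(CurveTracksError, ValueError):
    """Estimated co-metric is indefinite at too many points (bad bandwidth)."""


class UndefinedAngleError(CurveTracksError, ValueError):
    """An angle was requested for a zero-length vector or a center point."""
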