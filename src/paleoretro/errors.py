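"""Exception types shared across the package.

All inherit from :class:`ValueError` so callers that do not care about the
specific failure mode can catch a single base class.
"""


class LabellingError(ValueError):
    """Landmark labels missing, duplicated, or mismatched between inputs."""


class RankDeficientError(ValueError):
    """A configuration is too degenerate (e.g. collinear) for the operation."""


class SingularSystemError(ValueError):
    """A linear system cannot be solved (e.g. coincident TPS source points)."""


class DegenerateInputError(ValueError):
    """Zero-length or otherwise degenerate geometric input."""


class MeshInputError(ValueError):
    """A triangle mesh violates the basic structural invariants."""


class ProjectionError(ValueError):
    """A point that must lie on a surface is too far from it."""


class SpanningError(ValueError):
    """A curve anchor set does not cross the missing region."""


class OneSidedError(ValueError):
    """A section contour lies entirely on one side of the midsagittal plane."""


class ResolutionError(ValueError):
    """Requested mesh resolution is too coarse for the geometry."""


class ConfigurationError(ValueError):
    """A pipeline configuration is invalid; message lists all violations."""
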