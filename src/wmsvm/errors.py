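"""Exception hierarchy for the pipeline.

All errors derive from :class:`WmsvmError` so callers can catch the package's
failures with a single except clause; each also derives from ``ValueError``
to behave sensibly in generic code.
"""


class WmsvmError(Exception):
    """Base class for all package errors."""


class GeometryError(WmsvmError, ValueError):
    """Volume grids, voxel sizes, or effect geometry are inconsistent."""


class DimensionError(WmsvmError, ValueError):
    """Array shapes do not match the operation's contract."""


class ParameterError(WmsvmError, ValueError):
    """A scalar parameter is outside its valid range."""


class CohortError(WmsvmError, ValueError):
    """Cohort composition is invalid (missing group, too few subjects)."""


class LabelError(WmsvmError, ValueError):
    """Training labels do not contain both classes."""
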