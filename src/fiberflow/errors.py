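"""Typed error hierarchy.

Every loader and pipeline stage raises one of these instead of returning a
partially constructed object, so callers (and the CLI) can distinguish
malformed files from invalid parameters or degenerate data.
"""


class FiberflowError(Exception):
    """Base class for all package errors."""


class FormatError(FiberflowError):
    """A file does not follow the expected layout (missing column, duplicate
    frame index, unmatched startN/endN pair, ...)."""


class ValidationError(FiberflowError):
    """A file parsed but violates a domain invariant (event outside trial
    bounds, non-uniform time base, end before start, ...)."""


class ParameterError(FiberflowError):
    """An argument is outside its valid range (cutoff above Nyquist, analysis
    window outside the trace span, too few pairs, ...)."""


class DegenerateDataError(FiberflowError):
    """Data admit no answer: constant isosbestic regressor, zero variance in a
    normalization window, fitted baseline at zero."""


class GeometryError(FiberflowError):
    """Reference points do not define a board frame."""


class AlignmentError(FiberflowError):
    """Time bases cannot be brought into register (no overlap, mismatched
    relative-time grids, every event window outside the recording)."""


class ConfigError(FiberflowError):
    """A simulation or pipeline configuration is unsatisfiable."""
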