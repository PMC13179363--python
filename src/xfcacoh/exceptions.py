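"""Exception hierarchy for xfcacoh.

All package errors derive from :class:`XfcacohError` so callers can catch one
base class; subclasses mirror the failure categories of the pipeline stages.
"""


class XfcacohError(ValueError):
    """Base class for all xfcacoh errors."""


class AlignmentError(XfcacohError):
    """Two signal blocks are not time-aligned (fs or length mismatch)."""


class InsufficientDataError(XfcacohError):
    """Not enough samples/segments/epochs for the requested estimate."""


class ParameterError(XfcacohError):
    """A parameter is outside its valid range (e.g. band beyond Nyquist)."""


class ShapeError(XfcacohError):
    """Array dimensions do not match the operation's contract."""


class NumericalError(XfcacohError):
    """A numerical failure: singular matrix, broken monotonicity, etc."""


class FormatError(XfcacohError):
    """A file could not be parsed or is internally inconsistent."""
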