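"""Exception hierarchy shared by all pipeline stages.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3.
"""


class UpwellError(Exception):
    """Base class for all package errors."""


class ConfigError(UpwellError):
    """Invalid configuration or argument values."""


class DataError(UpwellError):
    """Invalid, inconsistent or degenerate data."""


class FormatError(DataError):
    """File does not contain the expected variable/structure."""


class AxisError(DataError):
    """Time axis is not contiguous monthly, or axes disagree."""


class AlignmentError(DataError):
    """Two inputs are not on the same grid or time axis."""


class EmptyRegionError(DataError):
    """A region mask selects no ocean cells."""


class DegenerateSeriesError(DataError):
    """A series has zero variance or too few valid points."""


class GapError(DataError):
    """A series has internal gaps where contiguity is required."""
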