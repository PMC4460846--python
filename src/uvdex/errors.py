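"""Exception hierarchy.

All package errors derive from :class:`UvdexError`; the three main branches
mirror where a problem originates: the experimental design, the data values,
or a user-supplied configuration.
"""


class UvdexError(Exception):
    """Base class for all uvdex errors."""


class ConfigurationError(UvdexError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DesignError(UvdexError, ValueError):
    """The sample design cannot support the requested operation."""


class DataError(UvdexError, ValueError):
    """Input values are malformed, non-finite or inconsistent."""


class MatrixParseError(DataError):
    """An expression-matrix file could not be parsed; includes location."""


class GmtParseError(DataError):
    """A gene-set (GMT) file could not be parsed; includes the line number."""


class StageError(UvdexError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
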