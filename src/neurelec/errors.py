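"""Exception hierarchy shared across the toolkit.

Every error raised on bad user input derives from :class:`NeurelecError`
so CLI wrappers can map them onto distinct exit codes.
"""


class NeurelecError(Exception):
    """Base class for all toolkit errors."""


class InvalidParameterError(NeurelecError, ValueError):
    """A physical or configuration parameter is outside its valid domain."""


class InputFormatError(NeurelecError, ValueError):
    """A file or table does not match its declared dialect."""


class EmptyInputError(InputFormatError):
    """An input file or table contains no records."""


class FitError(NeurelecError, RuntimeError):
    """A model fit failed; carries diagnostics rather than clipped values."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateFitError(FitError):
    """The data carry no information about one or more fit parameters."""


class PackingError(NeurelecError, RuntimeError):
    """Rejection sampling could not place the requested objects."""
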