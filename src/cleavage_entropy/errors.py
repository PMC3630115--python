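"""Exception hierarchy shared across the package."""


class CleavageEntropyError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CleavageEntropyError):
    """Input data violates a structural contract (missing residue, bad frequency...)."""


class WindowParseError(CleavageEntropyError):
    """A substrate window string could not be parsed.

    Attributes
    ----------
    position : int or None
        1-based offset of the offending character within the window,
        if the failure is localized.
    line : int or None
        1-based line number in the source file, when known.
    """

    def __init__(self, message, position=None, line=None):
        super().__init__(message)
        self.position = position
        self.line = line


class TableFormatError(CleavageEntropyError):
    """A cleavage table is structurally unusable (missing columns, no header)."""


class EmptyInputError(CleavageEntropyError):
    """An operation received no usable records."""


class ContractError(CleavageEntropyError):
    """A numeric precondition failed (unnormalized column, out-of-range score)."""


class UnavailableError(CleavageEntropyError):
    """A requested quantity cannot be computed (zero-count column, gated pair)."""


class UndefinedCorrelationError(CleavageEntropyError):
    """Correlation requested on a constant vector; the statistic is undefined."""
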