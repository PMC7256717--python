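"""Exception hierarchy shared across the package."""


class AcurulesError(Exception):
    """Base class for all package errors."""


class NormalizationError(AcurulesError):
    """A raw point label cannot be turned into a canonical item code."""


class ParseError(AcurulesError):
    """A transaction file is malformed.

    Carries the 1-based line (or row) number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(AcurulesError):
    """A domain invariant is violated (empty transaction, duplicate id, bad params)."""


class GuardError(AcurulesError):
    """A safety guard tripped (e.g. brute-force enumeration over too many items)."""
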