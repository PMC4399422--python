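"""Exception hierarchy shared across the package.

All errors raised by antioxcap derive from :class:`AntioxcapError`, so callers
can catch one base class. Subclasses also derive from the matching builtin
(``ValueError``, ``KeyError``) to stay friendly to generic error handling.
"""


class AntioxcapError(Exception):
    """Base class for all antioxcap errors."""


class InvalidParameterError(AntioxcapError, ValueError):
    """A physical parameter is out of its valid domain (e.g. epsilon <= 0)."""


class DegenerateAssayError(AntioxcapError, ValueError):
    """The assay carries no signal (control equals blank, or v0 = 0)."""


class SchemaError(AntioxcapError, ValueError):
    """A tabular input violates the expected CSV dialect.

    ``rows`` holds 1-based data-row numbers of the offending records when the
    violation is row-local (non-numeric absorbance, bad role, ...).
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        if rows:
            message = f"{message} (rows: {', '.join(map(str, rows))})"
        super().__init__(message)
        self.rows = rows or []


class InsufficientDataError(AntioxcapError, ValueError):
    """Too few points / concentrations / replicates for the requested fit."""


class CensoredInputError(AntioxcapError, ValueError):
    """A censored (no-effect) potency was supplied where a finite IC50 is required."""


class SoluteNotFoundError(AntioxcapError, KeyError):
    """The requested solute is absent from the plate or registry."""
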