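"""Exception hierarchy for lifeineq."""


class LifeineqError(Exception):
    """Base class for all package errors."""


class FormatError(LifeineqError):
    """A file does not follow the expected layout (e.g. a missing column)."""


class ValidationError(LifeineqError):
    """Data were parsed but violate a life-table invariant."""


class DegenerateInputError(LifeineqError):
    """The input is degenerate for the requested operation (e.g. no deaths)."""
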