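"""Exception hierarchy for panel validation and index computation."""


class TCMEquityError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(TCMEquityError):
    """Input file is missing a required column or has a malformed header."""


class ValidationError(TCMEquityError):
    """A record violates a domain invariant (e.g. nonpositive population)."""


class PartitionError(TCMEquityError):
    """A province name is not covered by the region partition in force."""


class AggregationError(TCMEquityError):
    """Panel cannot be aggregated (e.g. ragged province sets across years)."""


class InsufficientDataError(TCMEquityError):
    """Too few units or observations for the requested computation."""


class UndefinedIndexError(TCMEquityError):
    """The index is undefined on this input (zero totals, infinite divergence)."""


class ContractError(TCMEquityError):
    """A documented precondition was violated by the caller."""


class DegenerateModelError(TCMEquityError):
    """The fitted model is unusable (|a| ~ 0, constant series, S1 = 0)."""


class ConfigError(TCMEquityError):
    """Invalid synthetic-data or run configuration."""
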