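"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`McflferError`, so callers can catch one type at a pipeline boundary.
"""


class McflferError(Exception):
    """Base class for all errors raised by mcflfer."""


class SchemaError(McflferError, ValueError):
    """An input table is missing required columns or cannot be parsed."""


class ValidationError(McflferError, ValueError):
    """Values are parseable but violate a domain invariant (e.g. an
    observation's solute concentration is not one of the declared levels)."""


class PartitionDomainError(McflferError, ValueError):
    """Raw extraction quantities outside the domain of the partition
    formula (nonpositive volumes, or extracted amount >= total amount)."""


class EstimabilityError(McflferError, ValueError):
    """A least-squares fit has no residual degrees of freedom left after
    rank-deficient columns are dropped."""


class DegenerateTestError(McflferError, ValueError):
    """A hypothesis test whose null and alternative models coincide
    (no solute-concentration columns are estimable)."""


class UndefinedStatisticError(McflferError, ValueError):
    """A statistic with a zero denominator (e.g. Q^2 when all responses
    are identical)."""


class ConfigError(McflferError, ValueError):
    """A generator configuration is incomplete or inconsistent."""
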