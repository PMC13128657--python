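"""Exception types shared across the package."""


class HaiBurdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HaiBurdenError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(HaiBurdenError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class DataIntegrityError(HaiBurdenError, ValueError):
    """Referential-integrity violation between episode and infection tables."""


class MatchingError(HaiBurdenError, RuntimeError):
    """A matching design could not be carried out (e.g. degenerate propensity fit)."""


class RankDeficiencyError(HaiBurdenError, ValueError):
    """The regression design matrix is rank deficient."""
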