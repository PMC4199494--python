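"""Exception types shared across the package."""


class SweepABCError(Exception):
    """Base class for all package-specific errors."""


class UndefinedStatisticError(SweepABCError):
    """A statistic is mathematically undefined for the given input.

    Raised instead of silently returning 0 (e.g. Tajima's D with S = 0,
    Weir-Cockerham theta at a site monomorphic in both populations, EHH with
    fewer than two core-allele carriers, iHS with a zero iHH in one class).
    """


class ConditioningError(SweepABCError):
    """Rejection sampling failed to produce a trajectory segregating in both
    demes within the configured attempt cap."""

    def __init__(self, message: str, attempts: int = 0, accepted: int = 0):
        super().__init__(message)
        self.attempts = attempts
        self.accepted = accepted


class ConfigError(SweepABCError):
    """Invalid or out-of-range run configuration."""


class FormatError(SweepABCError):
    """Malformed input file (VCF, ms block, genetic map)."""
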