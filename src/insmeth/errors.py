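"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration/validation problems
exit 2, statistical degeneracies (zero variance, perfect separation,
empty margins) exit 3.
"""


class InsMethError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(InsMethError):
    """Invalid generator or pipeline configuration."""


class CohortValidationError(InsMethError):
    """A cohort table violates the schema or a value constraint."""


class DegenerateDataError(InsMethError):
    """Data too degenerate for the requested statistic (zero variance,
    perfect separation, empty group, all-zero margins...)."""
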