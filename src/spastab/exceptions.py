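"""Exception hierarchy.

All package-specific failures derive from :class:`SpastabError` so callers can
catch one base class at pipeline boundaries.
"""


class SpastabError(Exception):
    """Base class for all spastab errors."""


class SchemaError(SpastabError):
    """A delimited input file does not map onto the expected columns."""


class DuplicateKeyError(SpastabError):
    """A key column that must be unique (e.g. plot_id) contains duplicates."""


class DesignError(SpastabError):
    """A study design or generator configuration is internally inconsistent."""


class DomainError(SpastabError):
    """A value lies outside the mathematical domain of a statistic."""


class DegenerateStatisticError(SpastabError):
    """A statistic is undefined on this input (zero variance, empty plot...)."""


class SingularFitError(SpastabError):
    """A (weighted) least-squares system is singular or rank deficient."""
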