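"""Exception hierarchy.

All errors derive from :class:`MixedGamblesError` and from ``ValueError``, so
callers can catch either the package-specific or the generic class.
"""


class MixedGamblesError(ValueError):
    """Base class for all package errors."""


class InvalidDesignError(MixedGamblesError):
    """A choice-set design violates its constraints (non-positive maxima, too few levels)."""


class InvalidContextError(MixedGamblesError):
    """A decision-by-sampling comparison context is empty or malformed."""


class InvalidInputError(MixedGamblesError):
    """An operation received structurally invalid input (e.g. an empty common-gamble set)."""


class InsufficientDataError(MixedGamblesError):
    """Too few usable observations, fits, or agents to carry out the analysis."""


class InsufficientVariationError(MixedGamblesError):
    """A quantity that must vary across units is constant (e.g. a frozen parameter)."""
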