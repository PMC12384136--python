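"""Exception hierarchy shared across the package."""


class IccPermError(Exception):
    """Base class for all package-specific errors."""


class InvalidRatingsError(IccPermError, ValueError):
    """Raised when a ratings table violates the n x 2, finite, n >= 3 contract."""


class DegenerateDataError(IccPermError, ValueError):
    """Raised when a statistic is undefined for the given data.

    Examples: a fully constant ratings matrix (ICC denominator zero),
    MSW = 0 in the F test (perfect agreement), a constant rater column
    when the moment-based studentizer is required.
    """


class UnknownScenarioError(IccPermError, ValueError):
    """Raised for scenario names absent from (or unimplementable in) the registry."""


class InvalidParameterError(IccPermError, ValueError):
    """Raised for out-of-range user parameters (alpha, rho, B, ...)."""
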