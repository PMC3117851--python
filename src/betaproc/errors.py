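"""Exception types shared across the package."""


class BetaprocError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BetaprocError, ValueError):
    """An argument violates a documented precondition."""


class ModelInfeasibleError(BetaprocError):
    """A parameter combination yields an invalid model object (e.g. a
    trait-space covariance matrix that is not positive semidefinite)."""


class DegenerateInputError(BetaprocError):
    """Numerically degenerate input (e.g. all incidence log-weights -inf)."""


class UndefinedMetricError(BetaprocError):
    """A beta-diversity metric is undefined for the given communities
    (e.g. an empty community)."""


class UndefinedPartitionError(BetaprocError):
    """Variance partitioning is undefined (zero-variance response)."""


class SchemaError(BetaprocError):
    """A user-supplied file does not match the expected schema."""
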