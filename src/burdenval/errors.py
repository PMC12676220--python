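"""Exception types raised across the pipeline.

All inherit from :class:`BurdenvalError` so callers can catch broadly;
each subclass marks a distinct failure contract (schema vs vocabulary vs
join vs undefined statistic).
"""


class BurdenvalError(Exception):
    """Base class for all package errors."""


class SchemaError(BurdenvalError):
    """A required column is missing from an input table."""


class VocabularyError(BurdenvalError):
    """A sex or measure label is outside the controlled vocabulary."""


class DataError(BurdenvalError):
    """Input values violate a data contract (e.g. counts not derivable)."""


class JoinError(BurdenvalError):
    """Province labels fail to match across tables being joined."""


class ClusteringError(BurdenvalError):
    """Clustering is ill-posed (fewer distinct values than clusters)."""


class UndefinedStatisticError(BurdenvalError):
    """A disparity statistic has a zero or invalid denominator."""
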