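"""Exception hierarchy for the commdyn pipeline.

Every stage raises a subclass of :class:`CommdynError` so the pipeline driver
can attach the stage name before re-raising.
"""


class CommdynError(Exception):
    """Base class for all commdyn errors."""


class InvalidSpecError(CommdynError, ValueError):
    """A synthetic-data specification violates its invariants."""


class DataError(CommdynError, ValueError):
    """Input data are malformed (non-finite, wrong shape, missing values)."""


class ConfigError(CommdynError, ValueError):
    """A configuration value is inconsistent with the data it is applied to."""


class UndefinedCoherenceError(CommdynError, ValueError):
    """Coherence is undefined, e.g. for a zero-variance series."""


class UndefinedMetricError(CommdynError, ValueError):
    """A dynamics metric is undefined for the given partition (e.g. L = 1)."""


class DegenerateLayerError(CommdynError, ValueError):
    """A network layer carries no weight, so the modularity null model is undefined."""


class DegenerateInputError(CommdynError, ValueError):
    """An operation received input on which its result is undefined everywhere."""


class ConvergenceError(CommdynError, RuntimeError):
    """The optimizer exceeded its iteration cap while still improving."""


class InsufficientDataError(CommdynError, ValueError):
    """Too few observations for the requested statistical test."""


class StageError(CommdynError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
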