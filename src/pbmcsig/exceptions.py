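"""Exception hierarchy for the pipeline.

All package errors derive from :class:`PBMCSigError` so callers can catch
one base class; subclasses distinguish config, format, numerical-degeneracy
and orchestration failures.
"""


class PBMCSigError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PBMCSigError, ValueError):
    """Invalid configuration value or unknown configuration key."""


class FormatError(PBMCSigError, ValueError):
    """Malformed input file (ragged rows, duplicate ids, bad tokens)."""


class DomainError(PBMCSigError, ValueError):
    """Value outside the mathematical domain of an operation."""


class FitError(PBMCSigError, RuntimeError):
    """A model fit could not be carried out on the given data."""


class DegenerateDataError(FitError):
    """Data with zero variance (or otherwise degenerate) where variance is required."""


class InsufficientOverlapError(PBMCSigError, ValueError):
    """Too few mutually present values to compute a pairwise statistic."""


class UndefinedCorrelationError(PBMCSigError, ValueError):
    """Correlation undefined because one vector is constant on the shared positions."""


class StageError(PBMCSigError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
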