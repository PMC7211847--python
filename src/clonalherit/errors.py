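"""Exception hierarchy shared across the package.

Validation/configuration problems and data-integrity problems are kept
distinct so the CLI can map them to different exit codes (2 and 3).
"""


class ClonalHeritError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClonalHeritError):
    """Invalid configuration value, unknown mode token, bad parameter."""


class ValidationError(ConfigurationError):
    """Input violates a declared contract (e.g. unknown fate token)."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(ValidationError):
    """Data admits no fit (e.g. zero predictor variance)."""


class ContractError(ValidationError):
    """An operation was called on a cell that does not satisfy its precondition."""


class FormatError(ClonalHeritError):
    """Malformed file content; message names the first offending line."""


class IntegrityError(ClonalHeritError):
    """Cross-record inconsistency: dangling links, duplicates, cycles."""


class PedigreeError(IntegrityError):
    """Lineage structure violates binary division."""


class PipelineError(ClonalHeritError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
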