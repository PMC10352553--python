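"""Domain-specific exceptions raised across the package.

Every error a pipeline stage can raise deliberately derives from
:class:`EpiscoreError`, so callers (and the CLI) can distinguish invalid
scientific input from programming bugs.
"""


class EpiscoreError(Exception):
    """Base class for all deliberate errors raised by this package."""


class ScaleError(EpiscoreError):
    """A methylation matrix is on the wrong scale (beta vs M-value)."""


class ParameterError(EpiscoreError):
    """A numeric parameter is outside its admissible range."""


class CoverageError(EpiscoreError):
    """Panel coverage in the methylation matrix is below the threshold."""


class ZeroVarianceError(EpiscoreError):
    """A vector that must be standardized has no variance."""


class EmptyInputError(EpiscoreError):
    """An operation received zero samples or zero features."""


class EmptyPanelError(EpiscoreError):
    """Panel refinement produced a panel with no CpGs."""


class SchemaError(EpiscoreError):
    """A table does not match its declared schema."""


class DomainError(EpiscoreError):
    """A value lies outside its scientific domain (e.g. FI outside [0, 1])."""


class AlignmentError(EpiscoreError):
    """Two tables that must share a sample universe do not."""


class InsufficientReplicationError(EpiscoreError):
    """A compared group has fewer than two replicates."""


class DegenerateVarianceError(EpiscoreError):
    """A posterior variance used in a test statistic is not positive."""


class CollinearityError(EpiscoreError):
    """A regression design matrix is rank deficient."""


class SeparationError(EpiscoreError):
    """A logistic-type fit diverged, indicating (quasi-)complete separation."""


class DegenerateOutcomeError(EpiscoreError):
    """A binary or categorical outcome has fewer than two observed classes."""


class ConvergenceError(EpiscoreError):
    """An iterative maximum-likelihood fit failed to converge."""


class ValidationError(EpiscoreError):
    """A simulation or run configuration failed validation.

    Carries the list of offending fields in ``fields``.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []
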