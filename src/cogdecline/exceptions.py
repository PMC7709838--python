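"""Exception hierarchy.

Everything user-facing derives from :class:`CogDeclineError`; validation
problems (bad configs, malformed files, precondition violations) derive from
:class:`ValidationError` so the CLI can map them to exit code 2.
"""


class CogDeclineError(Exception):
    """Base class for all package errors."""


class ValidationError(CogDeclineError, ValueError):
    """Invalid input data or parameters."""


class ConfigurationError(ValidationError):
    """Invalid scenario / pipeline configuration."""


class ScoringError(ValidationError):
    """A trial group cannot be reduced to a score (e.g. no scorable trials)."""


class DegenerateNormativeError(ValidationError):
    """Control (normative) change SD too small to scale a Z score."""


class PipelineStageError(CogDeclineError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
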