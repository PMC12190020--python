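"""Exception hierarchy for cuprackit.

All package-specific failures derive from :class:`CuprackitError` so callers
can catch one base class at pipeline boundaries.
"""


class CuprackitError(Exception):
    """Base class for all cuprackit errors."""


class FormatError(CuprackitError):
    """A delimited-text input does not match the documented dialect."""


class DataValidationError(CuprackitError):
    """Input parsed but violates a domain invariant (names the offender)."""


class ConfigurationError(CuprackitError):
    """A parameter or configuration value is missing or inconsistent."""


class SingularDesignError(CuprackitError):
    """The mixture design matrix is rank-deficient for the requested model."""


class PipelineError(CuprackitError):
    """A workflow stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
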