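"""Exception hierarchy shared across the package."""


class FoodGRSError(Exception):
    """Base class for all package errors."""


class DomainError(FoodGRSError, ValueError):
    """An input value is outside its scientific domain (e.g. freq >= 1)."""


class ConfigurationError(FoodGRSError, ValueError):
    """Inputs are individually valid but mutually inconsistent
    (unknown rsID, food item not in the questionnaire, ...)."""


class FormatError(FoodGRSError, ValueError):
    """A file does not conform to its expected format."""


class SingularDesignError(FoodGRSError, ValueError):
    """The regression design matrix is rank deficient.

    The message names the offending term(s) where they can be identified.
    """


class BuildError(FoodGRSError, ValueError):
    """A food-specific risk score cannot be constructed (empty or
    duplicated SNP selection)."""


class PipelineError(FoodGRSError, RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
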