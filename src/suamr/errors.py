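"""Exception hierarchy shared across the package."""


class SuamrError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SuamrError, ValueError):
    """A scalar argument is outside its documented domain."""


class EmptyInputError(SuamrError, ValueError):
    """An operation received an empty table."""


class InsufficientDataError(SuamrError, ValueError):
    """Not enough records in a stratum to carry out the computation."""


class DegenerateInstrumentError(SuamrError, ValueError):
    """A genotype column is monomorphic and cannot serve as an instrument."""


class FitError(SuamrError, RuntimeError):
    """A regression model failed to converge."""

    def __init__(self, model: str, cause: str = ""):
        self.model = model
        msg = f"model '{model}' failed to fit"
        if cause:
            msg += f": {cause}"
        super().__init__(msg)


class SeparationError(FitError):
    """Complete or quasi-complete separation in a logistic model."""

    def __init__(self, model: str, cause: str = "complete separation"):
        super().__init__(model, cause)


class ScaleMismatchError(SuamrError, ValueError):
    """Effect estimates on incompatible scales were combined."""
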