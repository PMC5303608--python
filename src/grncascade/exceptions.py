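"""Exception hierarchy shared across the package."""


class GrnCascadeError(Exception):
    """Base class for all errors raised by grncascade."""


class FormatError(GrnCascadeError):
    """A file does not conform to the expected tabular format."""


class ValidationError(GrnCascadeError):
    """Inputs are well-formed but mutually inconsistent (e.g. unknown gene)."""


class OverdefinedModelError(GrnCascadeError):
    """Regression with n <= p: more predictors than the observations can support."""


class CollinearDesignError(GrnCascadeError):
    """Design matrix is rank deficient; the normal equations cannot be inverted."""


class DomainError(GrnCascadeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
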