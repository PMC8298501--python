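"""Exception hierarchy."""


class HeightModelsError(Exception):
    """Base class for package errors."""


class DomainError(HeightModelsError, ValueError):
    """Input violates a precondition (e.g. allele frequency outside (0, 1))."""


class SingularFitError(HeightModelsError, ValueError):
    """Design matrix is degenerate (zero weighted variance, collinear columns)."""


class ConfigurationError(HeightModelsError, ValueError):
    """A rule or threshold references a column that is not present."""
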