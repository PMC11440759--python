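"""Exception hierarchy shared across the package."""


class StephenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StephenError, ValueError):
    """Input file or value cannot be parsed as the expected format."""


class IntegrityError(StephenError, ValueError):
    """Parsed input violates a structural contract (duplicates, overlaps, negatives)."""


class InsufficientDataError(StephenError, ValueError):
    """Too few observations to carry out the requested computation."""


class NumericalError(StephenError, ArithmeticError):
    """A likelihood or optimisation step produced a non-finite value."""


class DegenerateModelError(StephenError, ValueError):
    """A fitted model is degenerate (e.g. exactly tied state means) and cannot be labelled."""
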