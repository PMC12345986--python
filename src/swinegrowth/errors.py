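"""Exception hierarchy shared across the package."""


class SwineGrowthError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SwineGrowthError, ValueError):
    """A model parameter violates its domain (e.g. non-positive A, B or K)."""


class InsufficientDataError(SwineGrowthError, ValueError):
    """Too few observations to perform the requested fit or test."""


class FitConvergenceError(SwineGrowthError, RuntimeError):
    """Nonlinear least squares failed to converge.

    Carries solver diagnostics in ``.diagnostics`` (dict).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(SwineGrowthError, ValueError):
    """An input table violates its declared schema.

    ``.problems`` lists human-readable messages, one per offending row/column,
    each prefixed with a line number where applicable.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        super().__init__(message)
        self.problems = problems or []
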