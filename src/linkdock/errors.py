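"""Exception hierarchy shared across the package."""


class LinkdockError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LinkdockError, ValueError):
    """Raised when an input violates a documented precondition."""


class ConfigurationError(LinkdockError, ValueError):
    """Raised for inconsistent protocol configuration (e.g. maximum < base recycles)."""


class PredictionError(LinkdockError, RuntimeError):
    """Raised when a predictor backend fails; carries the offending request."""

    def __init__(self, message, request=None):
        super().__init__(message)
        self.request = request


class EvaluationError(LinkdockError, RuntimeError):
    """Raised when model-quality evaluation cannot proceed (malformed native, missing atoms)."""


class DegenerateGeometryError(LinkdockError, RuntimeError):
    """Raised when a superposition problem is numerically degenerate."""
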