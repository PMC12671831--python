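"""Exception hierarchy shared across the package."""


class UmapsortError(Exception):
    """Base class for package errors."""


class FormatError(UmapsortError):
    """A file's contents do not match its declared layout."""


class ConfigError(UmapsortError):
    """Missing or inconsistent configuration / sidecar metadata."""


class ValidationError(UmapsortError):
    """An in-memory object violates a type invariant."""


class ParameterError(UmapsortError):
    """An operation was called with infeasible parameters."""


class GenerationError(UmapsortError):
    """The synthetic generator could not satisfy its constraints."""


class FitError(UmapsortError):
    """Nonlinear fit failed to converge from every start."""


class DegenerateFitError(FitError):
    """Input data carry no signal for the requested fit (e.g., flat F1)."""
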