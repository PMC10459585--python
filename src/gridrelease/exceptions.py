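"""Exception types shared across the package."""


class GridReleaseError(Exception):
    """Base class for all package errors."""


class DomainError(GridReleaseError, ValueError):
    """An argument is outside its physically meaningful domain."""


class FormatError(GridReleaseError, ValueError):
    """An input record or file violates the expected structure."""


class InsufficientDataError(GridReleaseError, ValueError):
    """Too few usable data points for the requested estimate."""


class PipelineError(GridReleaseError, RuntimeError):
    """One or more pipeline stages failed; message lists the units."""
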