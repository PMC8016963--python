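"""Exception hierarchy for the diffsen package."""


class DiffsenError(Exception):
    """Base class for all package errors."""


class ConfigError(DiffsenError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(DiffsenError):
    """A malformed input file; the message carries the path and line number."""


class HarmonizationError(DiffsenError):
    """A dataset whose matrices share no cell lines, or similar alignment failure."""


class InsufficientCellsError(DiffsenError):
    """Too few usable cell lines for a per-drug computation."""


class ModelingError(DiffsenError):
    """Degenerate modeling input (constant target, bad k, feature mismatch)."""


class TransferRefused(DiffsenError):
    """A cross-dataset run that cannot be evaluated (no shared features or
    too few test-only cells); carries a machine-readable ``reason``."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)
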