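"""Exception types shared across the package."""


class ChromodorError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChromodorError, ValueError):
    """A dataset, palette or result object violates a structural invariant."""


class GenerationError(ChromodorError, RuntimeError):
    """Synthetic-data generation cannot proceed (e.g. degenerate profile)."""


class UndefinedCorrelationError(ChromodorError, ValueError):
    """Pearson correlation is undefined (a constant pattern vector)."""
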