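"""Exception types shared across the package."""


class FlashscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FlashscreenError, ValueError):
    """Raised when inputs violate a documented contract (bad file, bad
    parameter, schedule/track mismatch).  Mapped to exit code 2 by the CLI."""


class ComputationError(FlashscreenError, RuntimeError):
    """Raised when a computation cannot proceed on otherwise valid inputs
    (e.g. every observation removed by a filter).  CLI exit code 3."""
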