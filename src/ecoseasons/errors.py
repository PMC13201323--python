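"""Exception types shared across the pipeline."""


class EcoseasonsError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(EcoseasonsError):
    """A configuration value violates its documented constraint."""


class DegenerateLandscapeError(EcoseasonsError):
    """The grid is too small (or otherwise unable) to realize the request."""


class StuckWalkerError(EcoseasonsError):
    """All candidate endpoints fell off the landscape repeatedly."""

    def __init__(self, message: str, position=None):
        super().__init__(message)
        self.position = position


class OrderingError(EcoseasonsError):
    """Input fixes are not strictly increasing in time."""


class OutOfBoundsError(EcoseasonsError):
    """Fixes fall outside the landscape extent."""

    def __init__(self, message: str, indices=None):
        super().__init__(message)
        self.indices = list(indices) if indices is not None else []


class DegenerateUDError(EcoseasonsError):
    """A utilization distribution cannot be estimated (e.g. zero spread)."""


class UndefinedCorrelationError(EcoseasonsError):
    """Correlation requested on a zero-variance series."""
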