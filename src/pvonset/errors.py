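"""Exception types shared across the package."""


class PvonsetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PvonsetError):
    """A column mapping, file path, or option is missing or inconsistent."""


class ValidationError(PvonsetError):
    """Input data violates a structural requirement (e.g. duplicate case ids)."""


class DesignMatrixError(PvonsetError):
    """The regression design matrix is rank-deficient.

    Carries the names of the offending (collinear) columns when they can be
    identified.
    """

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class FitError(PvonsetError):
    """A maximum-likelihood fit failed outright (too few data, degenerate sample)."""
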