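"""Exception types shared across the package."""


class KaryomorphError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KaryomorphError):
    """A measurement table is missing a required column."""


class ValidationError(KaryomorphError):
    """A measurement row or plate violates a domain invariant."""


class PairingError(KaryomorphError):
    """A plate cannot be paired into homologs (odd chromosome count)."""


class CalibrationError(KaryomorphError):
    """Template calibration could not reach the requested targets.

    Carries the best residuals achieved so the caller can see how far off
    each target was.
    """

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}
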