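"""Exception hierarchy shared across the analysis modules."""


class ChemosignalError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ChemosignalError, ValueError):
    """A caller-supplied parameter violates a documented precondition."""


class SchemaError(ChemosignalError, ValueError):
    """A trace file does not match its documented column schema.

    Carries ``row`` (0-based data-row index) when the offending location
    is known.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class EstimationError(ChemosignalError, RuntimeError):
    """Rotation/diameter estimation failed on degenerate input."""


class DetectionError(EstimationError):
    """No prominent diffraction ring found in the image."""


class FitError(ChemosignalError, RuntimeError):
    """A least-squares fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CalibrationError(ChemosignalError, RuntimeError):
    """Cross-talk / gauge-factor calibration failed (e.g. zero denominators)."""


class NormalizationError(ChemosignalError, RuntimeError):
    """Saturating-window normalization is inconsistent (max <= min)."""


class SignalTooWeakError(ChemosignalError, RuntimeError):
    """Every frame of an E-FRET series was masked by the denominator floor."""


class UndefinedBiasError(ChemosignalError, RuntimeError):
    """CW bias requested on a window containing no non-pause frames."""


class InsufficientReplicatesError(ChemosignalError, ValueError):
    """A statistical comparison needs >= 2 replicates per group."""


class PairingError(ChemosignalError, ValueError):
    """Paired test requested on conditions whose replicates do not match."""
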