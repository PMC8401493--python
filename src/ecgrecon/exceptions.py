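"""Exception hierarchy shared across the package."""


class EcgReconError(Exception):
    """Base class for all package-specific errors."""


class RecordFormatError(EcgReconError):
    """A record file could not be parsed (bad cell, bad header, ...)."""


class UnsupportedUnitError(RecordFormatError):
    """A WFDB signal declares physical units other than mV/uV/V."""


class LeadDefinitionError(EcgReconError):
    """A lead definition references electrodes absent from the record."""


class FilterSpecError(EcgReconError):
    """Invalid filter specification (cutoffs vs. Nyquist, order)."""


class SignalLengthError(EcgReconError):
    """A signal is too short for the requested operation."""


class InsufficientBeatsError(EcgReconError):
    """Fewer than two R peaks: RR intervals / P windows are undefined."""


class ConditioningError(EcgReconError):
    """Regression inputs are rank deficient (Gram condition number too high)."""

    def __init__(self, condition_number: float, bound: float):
        self.condition_number = condition_number
        self.bound = bound
        super().__init__(
            f"input Gram matrix condition number {condition_number:.3e} "
            f"exceeds bound {bound:.3e}; inputs are (near) rank deficient"
        )


class DivergenceError(EcgReconError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


class ConfigError(EcgReconError):
    """Invalid configuration value."""


class UndefinedMetricError(EcgReconError):
    """A figure of merit is undefined for the given signals (zero variance)."""
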