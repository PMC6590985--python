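"""Exception hierarchy shared across the package."""


class OtokitError(Exception):
    """Base class for all otokit errors."""


class InvalidParameterError(OtokitError, ValueError):
    """A parameter is outside its valid domain."""


class InsufficientDataError(OtokitError, ValueError):
    """Not enough spikes/trials/samples to compute the quantity."""


class DataError(OtokitError, ValueError):
    """Malformed or incompatible input data (NaNs, length mismatch, ...)."""


class CalibrationError(OtokitError, RuntimeError):
    """Threshold calibration could not reach the requested firing rate."""
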