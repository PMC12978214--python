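"""Exception types shared across the pipeline stages."""


class IcenucError(Exception):
    """Base class for all package-specific errors."""


class DataError(IcenucError):
    """Invalid or unusable input data (exit code 3 in the CLI)."""


class NoT50Error(DataError):
    """The fraction-frozen curve never reaches 0.5 for the requested dilution."""


class ExcludedPointError(DataError):
    """A frozen fraction of exactly 1 makes the Vali estimate divergent."""


class EmptySpectrumError(DataError):
    """Every candidate point of a dilution series was censored (f = 0 or f = 1)."""


class ConvergenceError(IcenucError):
    """Optimizer or calibration failure (exit code 4 in the CLI)."""


class CalibrationError(ConvergenceError):
    """No interfacial-energy scale in the search bracket reproduces the anchor."""
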