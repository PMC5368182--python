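"""Exception hierarchy shared across the package."""


class RrnThermoError(Exception):
    """Base class for all package-specific errors."""


class SequenceError(RrnThermoError):
    """Invalid nucleotide sequence input."""


class PrimerNotFoundError(RrnThermoError):
    """No primer binding site within the allowed mismatch budget."""


class AmbiguousPrimerSiteError(RrnThermoError):
    """More than one equally good primer binding site under strict matching."""


class PrimerOrientationError(RrnThermoError):
    """Forward site does not lie upstream of the reverse site."""


class UndefinedValueError(RrnThermoError):
    """A quantity (e.g. GC content of an all-ambiguous sequence) is undefined."""


class CalibrationError(RrnThermoError):
    """Thermometer calibration input is insufficient or degenerate."""


class QpcrError(RrnThermoError):
    """Standard-curve fitting or quantification failure."""


class GrowthAnalysisError(RrnThermoError):
    """Growth-curve analysis failure (no usable intervals, no growth, ...)."""


class GenerationError(RrnThermoError):
    """A synthetic-data generator could not satisfy its constraints."""


class ConfigError(RrnThermoError):
    """Invalid or unknown pipeline configuration."""
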