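"""Exception hierarchy for the scalebp pipeline.

Every stage raises a subclass of :class:`ScalebpError`, so callers (and the
CLI, which maps these onto exit codes) can distinguish configuration problems
from data-quality problems from resource-budget problems.
"""


class ScalebpError(Exception):
    """Base class for all scalebp errors."""


class ParseError(ScalebpError):
    """A text input could not be parsed (carries a line number when known)."""


class StructuralError(ScalebpError):
    """An input violates a structural invariant (e.g. unequal channel lengths)."""


class FramingError(ScalebpError):
    """A byte stream does not divide into whole sample frames."""


class RangeError(ScalebpError):
    """A sample falls outside the representable ADC range."""


class QualityError(ScalebpError):
    """A signal segment is too poor for fiducial detection."""


class CalibrationError(ScalebpError):
    """Cuff readings or resting calibration are missing or insufficient."""


class BudgetError(ScalebpError):
    """No model candidate fits the flash-memory budget."""


class ConfigError(ScalebpError):
    """A configuration value is invalid or inconsistent."""
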