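"""Exception hierarchy for the methylnode pipeline.

Every stage raises a subclass of :class:`MethylnodeError` so that the
pipeline driver can attach the stage name and offending record id before
re-raising.
"""


class MethylnodeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MethylnodeError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientCalibrationError(MethylnodeError, ValueError):
    """Too few (or degenerate) calibration points to fit a standard curve."""


class InvalidMeasurementError(MethylnodeError, ValueError):
    """A Ct / delta-Ct measurement is non-finite and not the undetected flag."""


class FormatError(MethylnodeError, ValueError):
    """An input table violates the expected schema; message names the row."""


class AdequacyError(MethylnodeError, ValueError):
    """A sample failed DNA-adequacy QC and cannot be quantified."""


class ConfigurationError(MethylnodeError, ValueError):
    """Missing or inconsistent run configuration (e.g. no curve for a gene)."""


class InvalidScoreError(MethylnodeError, ValueError):
    """A cumulative-methylation score is negative or non-finite."""


class NoFeasibleThresholdError(MethylnodeError, ValueError):
    """No candidate threshold attains the required specificity floor."""


class DegenerateInputError(MethylnodeError, ValueError):
    """An analysis needs both outcome classes (or non-constant data)."""
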