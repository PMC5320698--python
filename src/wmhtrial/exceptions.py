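"""Exception hierarchy.

All package errors derive from :class:`WMHTrialError` so callers can catch
one base class; configuration problems additionally derive from
``ValueError`` because they signal invalid inputs.
"""


class WMHTrialError(Exception):
    """Base class for all errors raised by wmhtrial."""


class ConfigurationError(WMHTrialError, ValueError):
    """An input design, config or plan field is invalid; message names the field."""


class DomainError(WMHTrialError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class DataError(WMHTrialError, ValueError):
    """A cohort table is missing required fields or rows."""


class CalibrationError(WMHTrialError, RuntimeError):
    """A calibration root-find could not bracket or converge."""


class SingularityError(WMHTrialError, ValueError):
    """A design matrix is rank-deficient; message names collinear columns."""


class DegenerateOutcomeError(WMHTrialError, ValueError):
    """An outcome has too few distinct values to fit the requested model."""
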