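"""Exception hierarchy for riskval.

Two broad families matter to callers (and to the CLI exit codes):
``RiskvalInputError`` for malformed inputs (exit code 2) and
``DegenerateAnalysisError`` for analyses that are undefined on the data
actually supplied, e.g. a single-class outcome (exit code 3).
"""


class RiskvalError(Exception):
    """Base class for all riskval errors."""


class RiskvalInputError(RiskvalError):
    """Malformed or inconsistent user input."""


class FormatError(RiskvalInputError):
    """A model-spec or cohort file failed to parse."""


class SchemaError(RiskvalInputError):
    """A parsed object violates its schema (unknown variable, duplicate term...)."""


class MissingDataError(RiskvalError):
    """A required predictor value is missing for a participant."""


class MissingOutcomeError(MissingDataError):
    """Both glucose measurements are missing; the outcome cannot be classified."""


class PairingError(RiskvalInputError):
    """Two prediction sets meant to be paired do not cover the same subjects."""


class DegenerateAnalysisError(RiskvalError):
    """The requested statistic is undefined on this input (e.g. no events)."""


class CalibrationError(RiskvalError):
    """The synthetic-cohort intercept calibration could not reach its target."""


class ConfigError(RiskvalInputError):
    """A simulation or missingness configuration is invalid."""
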