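"""Exception hierarchy for deglypk."""


class DeglypkError(Exception):
    """Base class for all package-specific errors."""


class ParameterValidationError(DeglypkError, ValueError):
    """A parameter value violates a sign/positivity constraint."""


class ParameterConsistencyError(DeglypkError, ValueError):
    """k_e disagrees with the sum of its elimination components."""


class ConfigurationError(DeglypkError, ValueError):
    """Incompatible route/sub-model combination or bad configuration input."""


class IntegrationError(DeglypkError, RuntimeError):
    """ODE propagation failed or violated mass balance."""


class SchemaError(DeglypkError, ValueError):
    """Dataset file does not match the expected column schema."""


class IntegrityError(DeglypkError, ValueError):
    """Dataset violates a uniqueness or value constraint."""


class UndefinedSplitError(DeglypkError, ZeroDivisionError):
    """A route-fraction denominator is zero."""


class UndefinedHalfLifeError(DeglypkError, ValueError):
    """Terminal phase does not decay; half-life undefined."""


class ObjectiveError(DeglypkError, ValueError):
    """The likelihood is undefined (e.g. non-positive prediction)."""


class InfeasibleFreezeError(DeglypkError, ValueError):
    """Biliary freezing arithmetic would produce a negative rate."""


class StagedCalibrationError(DeglypkError, RuntimeError):
    """A staged-calibration step is missing data or failed to fit."""


class DataError(DeglypkError, ValueError):
    """Dataset unusable for the requested operation (e.g. all BLQ)."""


class OraclePrecisionError(DeglypkError, RuntimeError):
    """Flux-integration horizon too short to account for the dose."""
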