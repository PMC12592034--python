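"""Exception hierarchy for stepwell."""


class StepwellError(Exception):
    """Base class for all stepwell errors."""


class ConfigError(StepwellError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(StepwellError, ValueError):
    """Input data violates a precondition (e.g. negative wear hours)."""


class DegenerateExposureError(StepwellError, ValueError):
    """Exposure distribution too degenerate to place strictly increasing knots."""


class SingularDesignError(StepwellError, ValueError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class BootstrapError(StepwellError, RuntimeError):
    """Bootstrap produced a distribution on which BCa constants are undefined."""


class ConvergenceError(StepwellError, RuntimeError):
    """Iterative estimator failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        self.last_iterate = last_iterate
        super().__init__(message)
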