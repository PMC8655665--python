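"""Exception hierarchy for the stratcare package."""


class StratCareError(Exception):
    """Base class for all package errors."""


class ConfigError(StratCareError):
    """Invalid or infeasible configuration (probabilities, proportions, bounds)."""


class InvalidDesignError(StratCareError):
    """Randomization design cannot be realized (too few clusters, odd block)."""


class NotACaseError(StratCareError):
    """RCSI requested for a patient below the clinical cutoff at baseline."""


class MissingEndpointError(StratCareError):
    """Endpoint score missing where a classification requires it."""


class MissingFeatureError(StratCareError):
    """A prognostic feature is missing at decision time (no silent imputation)."""


class ZeroMarginError(StratCareError):
    """Contingency-table statistic undefined because a margin is zero."""


class DegenerateMarginalsError(StratCareError):
    """Cohen's kappa undefined because expected agreement equals 1."""


class FitError(StratCareError):
    """Model fit failed (separation, degenerate outcome column)."""


class ConvergenceError(StratCareError):
    """Iterative algorithm failed to converge within max_iter."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class DataError(StratCareError):
    """Malformed input data (bad cell, negative count, missing column)."""


class StageError(StratCareError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
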