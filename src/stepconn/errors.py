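"""Exception hierarchy shared across the pipeline."""


class StepConnError(Exception):
    """Base class for all stepconn-specific failures."""


class ConfigurationError(StepConnError, ValueError):
    """Inconsistent simulation or pipeline configuration."""


class InputError(StepConnError, ValueError):
    """Invalid data handed to an operation (non-finite, constant, empty...)."""


class EstimationError(StepConnError, RuntimeError):
    """A statistical estimate could not be computed from the given data."""


class DesignMatrixError(StepConnError, ValueError):
    """Rank-deficient or otherwise unusable covariate design."""


class DegenerateGraphError(StepConnError, ValueError):
    """A graph operation is undefined, e.g. thresholding all-equal weights."""
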