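"""Exception types shared across the pipeline."""


class ScmotionError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ScmotionError, ValueError):
    """An argument is outside its documented domain."""


class ConfigValidationError(ScmotionError, ValueError):
    """A generator configuration is malformed; message lists offending keys."""


class WindowError(ScmotionError, ValueError):
    """An analysis window does not fit inside the trace."""


class DegenerateBaselineError(ScmotionError, ValueError):
    """Baseline fluorescence is non-positive; dF/F0 is undefined."""


class IntegrityError(ScmotionError, ValueError):
    """Event log and stimulus protocol are inconsistent."""


class IncompleteMatrixError(ScmotionError, ValueError):
    """A response matrix is missing one or more stimulus conditions."""


class DegenerateFitError(ScmotionError, ValueError):
    """The regression predictor has zero variance."""


class InsufficientDataError(ScmotionError, ValueError):
    """Too few observations for the requested statistic."""


class NoRFError(ScmotionError, ValueError):
    """No grid location passed the responsiveness criterion; cell is unmappable."""


class NoPreferenceError(ScmotionError, ValueError):
    """All responses non-positive; preferred direction is undefined."""
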