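"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`CbmnError`, so drivers can catch one
type and report the failing stage.
"""


class CbmnError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CbmnError):
    """A scoring table is structurally malformed (missing column, bad header)."""


class ValidationError(CbmnError):
    """A value violates a domain invariant (negative count, unknown timing...)."""


class MissingGroupError(CbmnError):
    """A required experimental arm or grouping key is absent from the data."""


class NonInvertibleCurveError(CbmnError):
    """The calibration curve has non-positive slope and cannot estimate doses."""


class SingularDesignError(CbmnError):
    """Regression design is singular (e.g. all calibration doses identical)."""


class NoRealDoseError(CbmnError):
    """Quadratic inverse has no real non-negative root at the requested frequency."""


class DegenerateVarianceError(CbmnError):
    """All groups have zero within-group variance; F statistic undefined."""


class PipelineError(CbmnError):
    """A stage of the orchestrated analysis failed; message carries the stage."""
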