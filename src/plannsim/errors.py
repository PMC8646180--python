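"""Exception types shared across the package."""


class PlannsimError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(PlannsimError, ValueError):
    """An argument violates an operation's preconditions."""


class DegenerateDataError(PlannsimError):
    """A dataset cannot support the requested operation (e.g. no events)."""


class CalibrationError(PlannsimError):
    """Coefficient calibration failed to bracket or reach its target."""


class UndefinedMetricError(PlannsimError):
    """A performance metric is undefined on the given data (e.g. no usable pairs)."""


class WeightSingularityError(PlannsimError):
    """An IPCW weight is infinite: the censoring survival estimate hit zero."""


class TuningError(PlannsimError):
    """Every grid point failed during cross-validation tuning."""
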