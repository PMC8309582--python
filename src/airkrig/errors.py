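"""Exception hierarchy for the airkrig pipeline.

Every stage raises a subclass of :class:`AirkrigError`; the CLI maps
:class:`ConfigError` to exit code 2 and every other subclass to exit code 1.
"""


class AirkrigError(Exception):
    """Base class for all airkrig errors."""


class InvalidInputError(AirkrigError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(AirkrigError):
    """A CSV file is missing required columns."""


class EmptyInputError(AirkrigError):
    """A file or collection that must be nonempty is empty."""


class ExtrapolationError(AirkrigError):
    """A time falls outside the fixed-station series span (no extrapolation)."""


class InvalidRouteError(InvalidInputError):
    """A route polyline is degenerate (zero length)."""


class InvalidFaultError(InvalidInputError):
    """A sensor fault specification is unusable (e.g. multiplicative bias 0)."""


class SimulationError(AirkrigError):
    """Gaussian field simulation failed (covariance factorization)."""


class DegenerateRegressorError(AirkrigError):
    """Calibration regressor has zero variance."""


class InsufficientDataError(AirkrigError):
    """Fewer usable points than the operation requires."""


class MissingCalibrationError(AirkrigError):
    """A sensor present in the data has no calibration coefficients."""


class EmptyVariogramError(AirkrigError):
    """All variogram bins are empty."""


class FitFailureError(AirkrigError):
    """Variogram model fitting failed from every start."""


class SingularSystemError(AirkrigError):
    """A kriging system stayed singular after deduplication and jitter."""


class DriftDegenerateError(AirkrigError):
    """KED drift matrix is rank-deficient (e.g. constant station values)."""

    def __init__(self, message: str, drift_name: str | None = None):
        super().__init__(message)
        self.drift_name = drift_name


class EmptyNeighborhoodError(AirkrigError):
    """No observation within the neighborhood search radius."""


class SplitError(AirkrigError):
    """A train/test split is degenerate or infeasible."""


class FoldError(AirkrigError):
    """A cross-validation fold has an empty test (or train) set."""


class ConfigError(AirkrigError):
    """The CLI configuration file is invalid (unknown keys, bad values)."""
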