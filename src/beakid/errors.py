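"""Named exception types shared across the pipeline."""


class BeakIdError(Exception):
    """Base class for all beakid errors."""


class InvalidViewError(BeakIdError, ValueError):
    """Beak view label is not one of {'upper', 'lower'}."""


class InvalidParameterError(BeakIdError, ValueError):
    """A numeric parameter is out of range or non-finite."""


class NoRoiFoundError(BeakIdError):
    """No contour passed the minimum-area filter."""


class DegenerateContourError(BeakIdError, ValueError):
    """Contour has no interior (zero area or fewer than 3 points)."""


class DegenerateHullError(BeakIdError, ValueError):
    """Convex hull of the input points is not a 2-D polygon (collinear input)."""


class BackboneUnavailableError(BeakIdError):
    """The requested deep-feature backbone cannot be instantiated."""


class HyperparameterSchemaError(BeakIdError, ValueError):
    """A classifier hyperparameter key is not part of the fixed schema."""
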