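"""Exception hierarchy for cardiomorph."""


class CardiomorphError(Exception):
    """Base class for all cardiomorph errors."""


class ValidationError(CardiomorphError, ValueError):
    """An input specification violates its contract."""


class PlacementError(CardiomorphError, RuntimeError):
    """Cell placement failed: requested density too high for the field."""


class FormatError(CardiomorphError, TypeError):
    """An image or mask has the wrong dtype/shape for the operation."""


class MeasurementError(CardiomorphError, ValueError):
    """A region is too small or degenerate for stable morphometry."""


class ThresholdError(CardiomorphError, ValueError):
    """Too few control cells to derive classification thresholds."""


class ProfileError(CardiomorphError, ValueError):
    """A population profile was requested for an empty cell list."""


class NormalizationError(CardiomorphError, ValueError):
    """A qPCR target has no reference-group records to normalise against."""


class GateError(CardiomorphError, ValueError):
    """A group is too small for the normality gate."""
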