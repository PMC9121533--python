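"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition; the message names the field."""


class CalibrationError(ValueError):
    """A calibrated quantity fell outside its configured physiological window."""


class ImputationError(ValueError):
    """Group-mean imputation impossible (e.g. a group with no observed values)."""


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not; the message names both."""
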