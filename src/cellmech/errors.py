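"""Exception hierarchy for the cellmech pipeline."""


class CellMechError(Exception):
    """Base class for all cellmech errors."""


class ThresholdError(CellMechError):
    """Raised when an image has no intensity range to threshold."""


class OverlapError(CellMechError):
    """Raised when synthetic shapes would overlap."""


class OutOfFrameError(CellMechError):
    """Raised when a synthetic shape does not fit inside the image frame."""


class PlacementError(CellMechError):
    """Raised when synthetic objects cannot be placed inside a mask."""


class NoContactError(CellMechError):
    """Raised when a force curve shows no detectable contact region."""


class DegenerateDataError(CellMechError):
    """Raised for inputs on which an estimator is undefined (e.g. all-zero MSD)."""
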