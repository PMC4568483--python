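"""Exception hierarchy for the spherotox pipeline.

Hard input problems (bad layouts, unreadable files, impossible calibrations)
raise; degenerate per-well image content never does — segmentation reports
area 0 with QC flags instead, so one bad well cannot abort a plate run.
"""


class SpherotoxError(Exception):
    """Base class for all spherotox errors."""


class LayoutError(SpherotoxError):
    """Plate layout is structurally invalid (duplicate wells, off-grid wells)."""


class ValidationError(SpherotoxError):
    """A field value violates its contract (negative concentration, bad role...)."""


class ManifestError(SpherotoxError):
    """Acquisition manifest is invalid (duplicate filenames, duplicate times)."""


class CalibrationError(SpherotoxError):
    """Well-grid calibration places a well outside the image."""


class GenerationError(SpherotoxError):
    """Synthetic rendering cannot honour the request (disk too large, no vehicle)."""


class InputError(SpherotoxError):
    """Inconsistent pipeline inputs (e.g. frames of different shapes)."""


class DataError(SpherotoxError):
    """Measurement table problem (duplicate time points for a well...)."""


class InsufficientDataError(DataError):
    """Too few usable points in the endpoint window to fit a rate."""


class NormalizationError(SpherotoxError):
    """Vehicle normalization impossible (no vehicle wells, non-positive mean)."""


class FitError(SpherotoxError):
    """Dose-response fit rejected its inputs (too few doses, flat data)."""


class FitNotConvergedError(SpherotoxError):
    """A fit ran but did not converge; distinct from :class:`FitError`."""


class UndefinedSeparationError(SpherotoxError):
    """Z'-factor undefined because the control means coincide."""
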