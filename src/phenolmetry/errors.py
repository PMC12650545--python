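"""Exception hierarchy.

All package errors derive from :class:`PhenolmetryError` so callers (and the
CLI) can distinguish user/data problems from genuine bugs.
"""


class PhenolmetryError(Exception):
    """Base class for all errors raised by phenolmetry."""


class FormatError(PhenolmetryError):
    """Malformed input file (bad header, non-numeric cell, duplicate well...)."""


class SchemaError(FormatError):
    """Input table is missing required columns or is empty."""


class ValidationError(PhenolmetryError):
    """Data violates a domain invariant (e.g. swapped acid/base traces)."""


class DomainError(PhenolmetryError):
    """Arithmetic precondition violated (e.g. non-positive acid-band absorbance)."""


class RangeError(PhenolmetryError):
    """Requested coordinate lies outside the measured grid."""


class LookupErrorPh(PhenolmetryError, KeyError):
    """Unknown group, well or field name."""


class DegenerateCalibrationError(PhenolmetryError):
    """Calibration inputs are degenerate (zero denominator, R_min >= R_max)."""


class InsufficientDataError(PhenolmetryError):
    """Too few usable points for the requested statistic."""


class DegenerateFitError(PhenolmetryError):
    """Regression input has zero variance in the regressor."""


class InfeasibleRecipeError(PhenolmetryError):
    """Charge balance has no root on [0, 14], or the titrant points the wrong way."""
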