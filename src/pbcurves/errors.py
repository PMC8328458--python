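"""Exception hierarchy.

Every failure mode gets a distinct class so callers (curve construction in
particular) can catch narrowly: a zero-denominator metric is skippable, a
count mismatch between a curve and its calibration spec is not.
"""


class PBCurvesError(Exception):
    """Base class for all package errors."""


class UndefinedMetricError(PBCurvesError):
    """A confusion-matrix ratio has a zero denominator at this threshold."""


class MissingHiddenCellsError(PBCurvesError):
    """Hidden cells m2/m3/m5/m6 requested but not present (real data)."""


class DegenerateCurveError(PBCurvesError):
    """Curve has zero x-span, or all naive precisions are identical."""


class TooFewPointsError(PBCurvesError):
    """Not enough defined curve points for percentile-window estimation."""


class InconsistentCountsError(PBCurvesError):
    """c / prevalence / sample counts contradict each other."""


class CountMismatchError(PBCurvesError):
    """Calibration spec counts disagree with the curve's source data."""


class InsufficientPresenceError(PBCurvesError):
    """Realized map has fewer presence cells than requested samples."""


class SchemaError(PBCurvesError):
    """Input table or report violates the expected schema."""
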