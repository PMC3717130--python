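"""Exception hierarchy for cohort validation, weighting, and calibration failures."""


class MapelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MapelError):
    """A cohort or target file does not match the expected column layout."""


class CohortParseError(MapelError):
    """A cell that must be numeric could not be parsed; names row and column."""


class CohortValidationError(MapelError):
    """A cohort violates a structural invariant (duplicate ids, missing values, N < 2)."""


class TargetConsistencyError(MapelError):
    """Trial-target bin counts disagree with the stated trial size."""


class TargetValidationError(MapelError):
    """Trial-target bins overlap, are unordered, or midpoints fall outside bins."""


class DegenerateAxisError(MapelError):
    """An axis is constant across the cohort, so a median split leaves a bin empty."""


class AllMassLostError(MapelError):
    """Every virtual patient received zero unnormalized prevalence weight."""


class DegenerateVarianceError(MapelError):
    """A variance-ratio test was requested with a zero standard deviation."""


class CoverageError(MapelError):
    """A response value falls outside every target bin (strict binning mode)."""


class AlignmentError(MapelError):
    """Scenario responses or weights do not align with the cohort's vp_ids."""


class SubsetBudgetError(MapelError):
    """The exhaustive best-subset search would exceed the combinatorial budget."""


class CalibrationFailureError(MapelError):
    """Ensemble construction exhausted its attempt budget with no acceptable population."""
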