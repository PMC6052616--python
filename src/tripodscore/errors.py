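"""Exception hierarchy for the tripodscore package."""

from __future__ import annotations


class TripodScoreError(Exception):
    """Base class for all package-specific errors."""


class ChecklistDefinitionError(TripodScoreError):
    """A checklist definition file is malformed or violates an invariant.

    The message names the offending item where one can be identified.
    """


class RecordValidationError(TripodScoreError):
    """One or more extraction records violate the schema.

    Attributes
    ----------
    violations : list of str
        Human-readable diagnostics, each carrying publication/model/element
        coordinates.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        preview = "\n  ".join(self.violations[:20])
        more = "" if len(self.violations) <= 20 else f"\n  … {len(self.violations) - 20} more"
        super().__init__(f"{len(self.violations)} record violation(s):\n  {preview}{more}")


class MergeError(TripodScoreError):
    """Two model-extraction parts cannot be merged."""


class ApplicabilityError(TripodScoreError):
    """An item was queried on a model to which it does not apply."""


class DegenerateInputError(TripodScoreError):
    """An operation received an input with no scoreable content."""


class CollinearityError(TripodScoreError):
    """The regression design matrix is rank deficient.

    Attributes
    ----------
    covariates : list of str
        Names of the covariates involved in the collinearity.
    """

    def __init__(self, covariates: list[str]):
        self.covariates = list(covariates)
        super().__init__(f"collinear covariates: {', '.join(self.covariates)}")
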