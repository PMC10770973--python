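"""Exception hierarchy for scimiss."""


class ScimissError(Exception):
    """Base class for all scimiss errors."""


class ConfigurationError(ScimissError):
    """Invalid generator, missingness or experiment configuration."""


class CohortValidationError(ScimissError):
    """A cohort table violates the schema invariants.

    Carries ``violations``, a list of (row_label, message) pairs.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.violations[:10])
        more = "" if len(self.violations) <= 10 else f" (+{len(self.violations) - 10} more)"
        super().__init__(f"cohort validation failed: {lines}{more}")


class StratificationError(ScimissError):
    """A bootstrap stratum is empty but has a positive target count."""


class FeasibilityError(ScimissError):
    """The requested missingness allocation is infeasible (implied p > 1)."""


class PreexistingMissingError(ScimissError):
    """The amputation target already contains missing entries."""


class EstimationError(ScimissError):
    """EM estimation cannot proceed (e.g. a variable entirely missing)."""


class SinglePatternError(ScimissError):
    """Little's test is undefined: only one missingness pattern (df = 0)."""


class InsufficientDataError(ScimissError):
    """Too few training rows to fit an imputation model."""


class DonorPoolError(ScimissError):
    """Donor-based matching requested more donors than observed rows."""


class FitError(ScimissError):
    """The analysis model design matrix is rank deficient."""
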