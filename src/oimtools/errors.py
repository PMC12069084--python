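"""Exception hierarchy shared across the package."""


class OimError(Exception):
    """Base class for all oimtools errors."""


class ValidationError(OimError):
    """A table, record or argument violates a structural invariant."""


class EmptyTableError(OimError):
    """No usable records remain after loading and filtering."""


class StrataError(OimError):
    """Subcategory strata are missing, empty or inconsistent with a weight scheme."""


class MatchError(OimError):
    """Food categories do not match between consumption and occurrence data."""


class MissingOccurrenceError(MatchError):
    """A consumed category has no mean occurrence available."""


class DegenerateWeightsError(OimError):
    """Consumption-derived weights cannot be formed (zero total consumption)."""


class FitError(OimError):
    """Censored maximum-likelihood fitting failed to converge."""


class ResamplingError(OimError):
    """A bootstrap resampling plan cannot be executed (e.g. empty stratum)."""
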