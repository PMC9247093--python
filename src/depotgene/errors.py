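"""Exception hierarchy shared across the pipeline stages."""


class DepotgeneError(Exception):
    """Base class for all package-specific errors."""


class DegenerateDesignError(DepotgeneError):
    """Design matrix is rank-deficient (e.g. a constant covariate within a sex)."""


class InvalidValueError(DepotgeneError):
    """An input value violates a domain constraint (e.g. non-positive depot volume)."""


class AlignmentError(DepotgeneError):
    """Effect/other alleles of two records for the same variant do not match."""


class SpecError(DepotgeneError):
    """A simulation spec is internally inconsistent."""


class DataError(DepotgeneError):
    """Malformed input data (e.g. dosage outside [0, 2])."""


class InsufficientDataError(DepotgeneError):
    """Too few observations for the requested computation."""


class ConvergenceError(DepotgeneError):
    """An iterative fit failed to converge within its caps."""
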