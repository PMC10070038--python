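"""Exception hierarchy for binpower."""


class BinpowerError(Exception):
    """Base class for all binpower errors."""


class InvalidParameterError(BinpowerError, ValueError):
    """A parameter is outside its admissible range or contradicts another."""


class InfeasibleModelError(BinpowerError, ValueError):
    """The requested marginal structure cannot be realized.

    Raised, e.g., when a continuous covariate's marginal variance is not
    large enough to accommodate the requested genotype dependence.
    """


class UnresolvedModelError(BinpowerError, RuntimeError):
    """An operation requires gleaned intercepts/variances that are missing."""


class ConvergenceError(BinpowerError, RuntimeError):
    """A numerical routine (root finder, IRLS) failed to converge."""


class SingularInformationError(BinpowerError, RuntimeError):
    """The estimated Fisher information matrix is singular or near-singular."""
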