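"""Exception hierarchy for pcmodel."""


class PCModelError(Exception):
    """Base class for all pcmodel errors."""


class InvalidDesignError(PCModelError, ValueError):
    """A component model or design matrix is structurally invalid."""


class UnidentifiableModelError(PCModelError, ValueError):
    """The requested model has a structural ambiguity that cannot be resolved."""


class SingularCovarianceError(PCModelError, ValueError):
    """The marginal covariance V = Z G Z' + I sigma_eps^2 is singular."""


class NumericalFailureError(PCModelError, RuntimeError):
    """An iterative routine produced a non-finite quantity.

    Carries the iteration index at which the failure occurred.
    """

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
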