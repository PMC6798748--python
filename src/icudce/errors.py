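"""Exception hierarchy for icudce."""


class IcuDceError(Exception):
    """Base class for all icudce errors."""


class ConfigError(IcuDceError):
    """Invalid attribute or run configuration."""


class DesignError(IcuDceError):
    """Design construction or search failure."""


class SingularDesignError(DesignError):
    """Design information matrix is singular (unidentifiable design)."""


class DataError(IcuDceError):
    """Malformed or inconsistent choice data."""


class EstimationError(IcuDceError):
    """Likelihood maximization failure."""


class SeparationError(EstimationError):
    """Perfect separation detected during logit fitting."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"perfect separation suspected on column {column!r}")


class ConvergenceError(EstimationError):
    """Optimizer failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_beta=None):
        self.last_beta = last_beta
        super().__init__(message)
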