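"""Exception hierarchy shared across the package."""


class ColliderBiasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ColliderBiasError, ValueError):
    """A scenario or DAG configuration violates its validity constraints."""


class DegenerateSampleError(ColliderBiasError, ValueError):
    """Too few observations (or an empty selection class) for the requested statistic."""


class SingularDesignError(ColliderBiasError, ValueError):
    """The regression design matrix is rank-deficient (e.g. zero variance in the score)."""


class NumericalError(ColliderBiasError, RuntimeError):
    """A numerical routine (quadrature / root-finding) failed to converge."""
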