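"""Exception hierarchy for spherepace."""


class SpherePaceError(Exception):
    """Base class for all spherepace errors."""


class GeometryError(SpherePaceError):
    """Invalid geometric input (off-sphere point, antipodal log, bad composition)."""


class ConvergenceError(SpherePaceError):
    """An iterative solver failed to converge within its iteration budget."""


class BandwidthError(SpherePaceError):
    """A kernel window is empty or rank-deficient even after adaptive widening."""


class ModelError(SpherePaceError):
    """A model-fitting stage received inputs it cannot handle."""


class DataValidationError(SpherePaceError):
    """Tabular input violates the long-format contract (with row numbers)."""
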