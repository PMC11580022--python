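"""Package-wide exception types."""


class MemtideError(Exception):
    """Base class for all memtide errors."""


class DomainError(MemtideError, ValueError):
    """An input violates a physical-domain precondition (sign, range, units)."""


class FitError(MemtideError, RuntimeError):
    """A model fit failed to converge or the data cannot constrain it."""


class GeometryError(MemtideError, ValueError):
    """Tracked geometry is inconsistent (e.g. tether base off the contour)."""


class SchemaError(MemtideError, ValueError):
    """A table does not match its declared column schema or ordering rules."""


class UndefinedStatisticError(MemtideError, ValueError):
    """The requested statistic is undefined on this trace (e.g. no dip)."""
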