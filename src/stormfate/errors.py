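"""Exception hierarchy for the simulator.

All errors derive from :class:`StormfateError` so callers can catch the
package's failures with a single except clause; most also derive from the
matching builtin (``ValueError``/``RuntimeError``) for ergonomic testing.
"""


class StormfateError(Exception):
    """Base class for all package errors."""


class FormatError(StormfateError, ValueError):
    """A file does not conform to its expected on-disk format."""


class DimensionError(StormfateError, ValueError):
    """Array/grid shapes are inconsistent."""


class ValidationError(StormfateError, ValueError):
    """A parameter or input failed a documented bound or constraint."""


class ContinuityError(StormfateError, ValueError):
    """A daily series has gaps or duplicate dates."""


class DomainError(StormfateError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class TopologyError(StormfateError, RuntimeError):
    """The flow graph is cyclic or contains an unresolved pit."""


class AlignmentError(StormfateError, ValueError):
    """Two series that must share a date axis do not."""


class CoverageError(StormfateError, ValueError):
    """A requested date lies outside the simulated span."""


class ConservationError(StormfateError, RuntimeError):
    """A mass or water balance failed to close within tolerance."""
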