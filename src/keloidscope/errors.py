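"""Exception hierarchy for keloidscope.

Each error class corresponds to one failure mode of the public API
(invalid generator spec, empty mask region, malformed colorbar LUT, ...)
so callers and the CLI can map failures to distinct exit codes.
"""


class KeloidscopeError(Exception):
    """Base class for all package errors."""

    code = 1


class InvalidSpecError(KeloidscopeError):
    """Scene specification violates its invariants."""

    code = 10


class InsufficientNError(InvalidSpecError):
    """Requested dataset too small for the number of stages."""

    code = 11


class EmptyRegionError(KeloidscopeError):
    """An operation requiring a nonempty mask received an empty one."""

    code = 20


class InvalidLUTError(KeloidscopeError):
    """Colorbar LUT fails validation (too few anchors, non-monotone PU)."""

    code = 30


class AmbiguousLUTError(InvalidLUTError):
    """Same color mapped to different perfusion values."""

    code = 31


class InvalidInputError(KeloidscopeError):
    """Generic precondition failure on user input."""

    code = 40


class InvalidShapeError(InvalidInputError):
    """Image shape incompatible with the requested patch tiling."""

    code = 41


class EmptySelectionError(KeloidscopeError):
    """Patch selection retained zero patches."""

    code = 50


class UndefinedMetricError(KeloidscopeError):
    """A confusion-matrix metric has a zero denominator."""

    code = 60


class InvalidKError(InvalidInputError):
    """Cross-validation fold count incompatible with class counts."""

    code = 61
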