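"""Exception hierarchy for the stormring pipeline.

Every error raised on a per-structure basis derives from
:class:`StormringError` so cohort drivers can record the failure and
continue with the remaining structures.
"""


class StormringError(Exception):
    """Base class for all stormring errors."""


class FormatError(StormringError):
    """A molecule-list file violates the expected tabular format."""


class EmptyInputError(StormringError):
    """An operation received (or produced) zero localization events."""


class InsufficientDataError(StormringError):
    """Too few events for the requested statistical operation."""


class DegenerateDataError(StormringError):
    """Input geometry carries no usable information (e.g. coincident points)."""


class GeometryError(StormringError):
    """A geometric fit is impossible (collinear points, < 3 points, ...)."""


class FitFailureError(StormringError):
    """A nonlinear fit failed to converge after bounded restarts."""


class InfeasibleOffsetError(StormringError):
    """An observed direct/indirect offset is inconsistent with the antibody
    geometry model (|offset| exceeds the maximal reachable displacement)."""


class UsageError(StormringError):
    """An operation was called with arguments violating its contract."""


class ValidationError(StormringError):
    """A configuration object violates its invariants.

    ``fields`` lists the offending field names.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = list(fields or [])
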