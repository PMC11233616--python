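"""Exception hierarchy.

All package errors derive from :class:`AneumorphError` so callers (and the
CLI) can distinguish bad input from internal failure with one except clause.
"""


class AneumorphError(Exception):
    """Base class for all aneumorph errors."""


class InputError(AneumorphError):
    """Missing or unparseable input file."""


class ValidationError(AneumorphError):
    """A domain invariant is violated; ``field`` names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class GeometryError(AneumorphError):
    """A geometric operation cannot proceed (degenerate or inconsistent input)."""


class ComputationError(AneumorphError):
    """A derived quantity is undefined; ``index`` names it."""

    def __init__(self, index: str, message: str):
        self.index = index
        super().__init__(f"{index}: {message}")


class SchemaError(AneumorphError):
    """Feature-table schema mismatch."""


class EncodingError(AneumorphError):
    """Unknown categorical value during feature encoding."""


class TrainingError(AneumorphError):
    """Model training preconditions not met."""


class MetricError(AneumorphError):
    """Evaluation metric undefined for the given labels/scores."""
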