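"""Exception hierarchy shared across the package.

Every validation error carries enough context (file, row, offending value)
to locate the problem in the user's input.
"""


class SpongescanError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpongescanError):
    """Base class for input-validation failures (CLI exit code 2)."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class IdentifierError(ValidationError):
    """A feature identifier does not match the convention for its RNA type."""


class SampleCountError(ValidationError):
    """A condition has fewer than the minimum required samples."""


class ShapeError(ValidationError):
    """Duplicate identifiers, non-numeric cells, or otherwise malformed table."""


class FormatError(ValidationError):
    """A structured text file (e.g. GMT) violates its format."""


class ConfigError(ValidationError):
    """Invalid run or fixture configuration."""


class EmptyInputError(SpongescanError):
    """An operation received an empty table where at least one row is required."""


class CalibrationError(SpongescanError):
    """No validated interaction qualifies for affinity-cutoff calibration."""


class MissingLengthError(SpongescanError):
    """A circRNA target has no entry in the spliced-length table."""


class DegenerateBackgroundError(SpongescanError):
    """The binding-site background is empty (grand total of sites is zero)."""


class WeightError(SpongescanError):
    """Non-positive or non-normalizable criterion weights."""


class DegenerateSetError(SpongescanError):
    """A gene set that covers the entire ranked list."""


class NotFoundError(SpongescanError):
    """A network selection matched no score-matrix row."""


class EmptyQueryError(SpongescanError):
    """An enrichment query gene set is empty."""


class EmptyResultError(SpongescanError):
    """The candidate set was emptied by a pipeline stage (CLI exit code 3)."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no candidate pairs survive stage '{stage}'")
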