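"""Exception hierarchy shared across the package."""


class MSLVError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(MSLVError):
    """Raised when landmark geometry is degenerate (e.g. coincident points)."""


class LevelError(MSLVError):
    """Raised for unknown levels or levels outside an operation's valid range."""


class SchemaError(MSLVError):
    """Raised when a cohort/patient JSON document violates the landmark schema.

    The message always names the offending patient id (when known) and the
    JSON path of the bad field.
    """


class ExclusionError(MSLVError):
    """Raised when a patient violating a study exclusion criterion reaches an
    operation that requires an analyzable patient (e.g. UIV cranial to T2)."""


class ZeroCellError(MSLVError):
    """Raised by the Woolf odds-ratio when a 2x2 cell is zero and continuity
    correction was not requested."""


class SeparationError(MSLVError):
    """Raised when logistic regression detects (quasi-)complete separation."""


class InsufficientDataError(MSLVError):
    """Raised when a statistical test receives too few observations."""
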