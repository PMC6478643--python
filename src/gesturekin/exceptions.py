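"""Exception types shared across the package."""


class GestureKinError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GestureKinError):
    """An input table is missing required columns."""


class TableParseError(GestureKinError):
    """A cell in an input table could not be parsed."""


class WindowValidationError(GestureKinError):
    """An act-window file violates the ordering/non-overlap invariants."""


class DataQualityError(GestureKinError):
    """A feature requires joint samples that are missing or untracked."""


class SpecError(GestureKinError):
    """A synthetic act specification is internally inconsistent."""
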