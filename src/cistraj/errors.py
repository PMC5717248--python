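"""Exception hierarchy.

All package errors derive from :class:`CistrajError` so callers can catch a
single base class; the CLI maps :class:`ConfigurationError` to exit code 2 and
every other :class:`CistrajError` to exit code 1.
"""


class CistrajError(Exception):
    """Base class for all cistraj errors."""


class ParseError(CistrajError):
    """A coordinate or table file could not be parsed."""


class SchemaError(CistrajError):
    """A tabular input is missing required columns."""


class ValidationError(CistrajError):
    """An input violates a documented invariant (range, sign, emptiness)."""


class SelectionError(CistrajError):
    """An atom/residue selection is empty, overlapping or unresolvable."""


class ShapeError(CistrajError):
    """Atom counts between a trajectory and its topology disagree."""


class CompletenessError(CistrajError):
    """Required atoms or parameter rows are missing; message lists them."""


class GeometryError(CistrajError):
    """Degenerate geometry (collinear/coincident points) for an angle."""


class ConstructionError(CistrajError):
    """A synthetic-data generator could not satisfy its constraints."""


class ConfigurationError(CistrajError):
    """Pipeline configuration invalid or stage prerequisites missing."""


class UsageError(CistrajError):
    """A function was called with an unsupported option (e.g. file format)."""
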