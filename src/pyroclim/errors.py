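"""Exception hierarchy.

All user-facing errors derive from :class:`PyroclimError` so callers can
catch one type; the subclasses distinguish bad parameters from degenerate
data (constant series, empty matrices) and malformed files.
"""


class PyroclimError(Exception):
    """Base class for all pyroclim errors."""


class InvalidParameterError(PyroclimError, ValueError):
    """A parameter is outside its admissible range."""


class InvalidInputError(PyroclimError, ValueError):
    """Input data violate a precondition (negative values, span mismatch...)."""


class DegenerateInputError(PyroclimError, ValueError):
    """Input is formally valid but statistically degenerate (constant, empty)."""


class FormatError(PyroclimError, ValueError):
    """A file does not conform to the expected on-disk format."""
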