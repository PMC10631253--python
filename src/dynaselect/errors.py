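"""Exception hierarchy.

``ParseError`` covers malformed input files; ``ValidationError`` covers
inputs that parse but violate a documented invariant; ``DegenerateInputError``
covers geometrically degenerate situations in which the two-dimensional
reduction is undefined (identical products, parallel product directions,
modes orthogonal to the bifurcation plane, zero stream width).
"""


class DynaselectError(Exception):
    """Base class for all package errors."""


class ParseError(DynaselectError):
    """A file does not follow its declared format."""


class ValidationError(DynaselectError):
    """Parsed input violates a documented invariant."""


class DegenerateInputError(DynaselectError):
    """Geometry is degenerate and the 2D bifurcation analysis is undefined."""
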