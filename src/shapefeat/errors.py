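"""Exception hierarchy shared across the package."""


class ShapefeatError(Exception):
    """Base class for all shapefeat errors."""


class SizeError(ShapefeatError, ValueError):
    """A shape or image does not fit the requested geometry."""


class ParameterError(ShapefeatError, ValueError):
    """A parameter value is degenerate or outside its admissible range."""


class EmptyMaskError(ShapefeatError, ValueError):
    """An operation that requires object pixels received none."""


class MultiComponentError(ShapefeatError, ValueError):
    """A single-connected-component mask was required; rejoin first."""


class TooFewPixelsError(ShapefeatError, ValueError):
    """The object has too few pixels for the requested feature set."""
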