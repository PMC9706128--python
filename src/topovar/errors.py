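"""Exception hierarchy shared across the pipeline stages."""


class TopovarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TopovarError):
    """An input file could not be parsed under the declared format."""


class ConsistencyError(TopovarError):
    """Frames of an ensemble do not share an identical residue list."""


class DegenerateInputError(TopovarError):
    """Too few points remain for the requested topological computation."""


class InsufficientDataError(TopovarError):
    """Fewer observations than the model needs for a proper posterior."""
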