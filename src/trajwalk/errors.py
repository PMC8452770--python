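"""Exception hierarchy shared across the package."""


class TrajwalkError(Exception):
    """Base class for all package errors."""


class ParameterError(TrajwalkError, ValueError):
    """An argument is outside its admissible range."""


class DataError(TrajwalkError, ValueError):
    """Input data violates a structural requirement (non-finite, empty...)."""


class GraphError(TrajwalkError, ValueError):
    """A graph violates a structural precondition (zero-degree node...)."""


class FormatError(TrajwalkError, ValueError):
    """A file does not conform to its declared on-disk format."""


class LookupFailure(TrajwalkError, KeyError):
    """A requested label or id cannot be resolved."""


class DegenerateParameterError(ParameterError):
    """A parameter combination makes an operator numerically singular."""


class CapacityError(TrajwalkError, ValueError):
    """Problem size exceeds an exact algorithm's stated budget."""
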