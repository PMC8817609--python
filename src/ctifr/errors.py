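"""Exception types shared across the package."""


class CtifrError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CtifrError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(CtifrError, ValueError):
    """A serialized tree/config does not conform to its declared schema."""


class DegeneratePhysicsError(CtifrError, RuntimeError):
    """The computed pressure field left the physical regime (P <= 0).

    Raised by the solver when the prescribed flow cannot be pushed through
    the geometry at the given inlet pressure; carries the offending segment
    and point index.
    """

    def __init__(self, message: str, segment_id: int | None = None,
                 point_index: int | None = None):
        super().__init__(message)
        self.segment_id = segment_id
        self.point_index = point_index
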