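"""Exception hierarchy shared across the package."""


class DendromatchError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(DendromatchError, ValueError):
    """Malformed Newick input.

    ``offset`` is the 0-based character offset of the offending character
    when it can be determined, else ``None``.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class ValidationError(DendromatchError, ValueError):
    """A structurally parsed tree violates a dendrogram invariant."""


class IdentityError(DendromatchError, ValueError):
    """A leaf name cannot be decomposed into sample type + replicate id."""


class ParameterError(DendromatchError, ValueError):
    """An algorithm parameter is outside its allowed range."""


class FixtureError(DendromatchError, ValueError):
    """A synthetic-tree perturbation's precondition is not met."""
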