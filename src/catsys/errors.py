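"""Exception hierarchy.

Everything raised on purpose derives from :class:`CatsysError`, so callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class CatsysError(Exception):
    """Base class for all errors raised by catsys."""


class CompositionError(CatsysError):
    """Composition of two maps whose middle objects disagree."""


class CodomainMismatchError(CatsysError):
    """Pullback of two maps with different codomains."""


class DomainMismatchError(CatsysError):
    """Pushout of two maps with different domains."""


class NotParallelError(CatsysError):
    """Equalizer/coequalizer of maps that are not a parallel pair."""


class EnumerationCapError(CatsysError):
    """An exhaustive enumeration would exceed the configured cap."""

    def __init__(self, required: int, cap: int, what: str = "maps"):
        self.required = required
        self.cap = cap
        super().__init__(
            f"enumeration of {what} needs {required} candidates, cap is {cap}"
        )


class ShapeError(CatsysError):
    """Malformed shape graph, or a cyclic shape without a path bound."""


class DiagramError(CatsysError):
    """Objects/maps inconsistent with the shape they decorate."""


class NoFactorizationError(CatsysError):
    """A claimed cone does not factor through the limit cone."""


class MalformedSpecError(CatsysError):
    """A DomainSpec violating its style's shape requirements."""


class UnknownFixtureError(CatsysError):
    """Request for a fixture name not in the catalog."""


class UnknownComponentError(CatsysError):
    """Membership query with a component drawn from no declared set."""


class SelectorError(CatsysError):
    """Inference selector matching no apex element, or more than one."""


class WrongStyleError(CatsysError):
    """Operation applied to a realized relation of an unsupported style."""


class SchemaError(CatsysError):
    """Domain-spec document violating the JSON dialect's schema."""

    def __init__(self, location: str, message: str):
        self.location = location
        super().__init__(f"{location}: {message}")


class IntegrityError(CatsysError):
    """Domain-spec document referencing undeclared sets, maps or elements."""
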