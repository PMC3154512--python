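"""Finite sets and total maps: the ambient category.

Objects are finite sets of opaque string labels, morphisms are total
functions between them.  Ordered pairs and triples are encoded as
parenthesized comma-joined labels (``"(mare,colt)"``), so the apex of one
construction is a plain object usable by the next.  All element orderings
are lexicographic, which makes every downstream enumeration deterministic.

Equality is extensional throughout: two sets are equal when they hold the
same labels (names are display-only), and two maps are equal when their
domains, codomains and per-element assignments agree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional

from .errors import CompositionError, EnumerationCapError

#: Default ceiling on exhaustive map enumeration (candidate count).
DEFAULT_ENUM_CAP = 10**6


def tuple_label(parts: Iterable[str]) -> str:
    """Encode an ordered tuple of labels as a single label, ``(a,b,c)``."""
    return "(" + ",".join(parts) + ")"


def split_label(label: str) -> tuple[str, ...]:
    """Invert :func:`tuple_label`, respecting nested parentheses.

    ``"((a,b),c)"`` splits into ``("(a,b)", "c")``; a non-tuple label
    raises ``ValueError``.
    """
    if not (label.startswith("(") and label.endswith(")")):
        raise ValueError(f"not a tuple label: {label!r}")
    inner = label[1:-1]
    if inner == "":
        return ()
    parts: list[str] = []
    depth = 0
    current: list[str] = []
    for ch in inner:
        if ch == "," and depth == 0:
            parts.append("".join(current))
            current = []
        else:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            current.append(ch)
    if depth != 0:
        raise ValueError(f"unbalanced parentheses in label: {label!r}")
    parts.append("".join(current))
    return tuple(parts)


def is_tuple_label(label: str) -> bool:
    try:
        split_label(label)
        return True
    except ValueError:
        return False


class FinSet:
    """A finite set of distinct string labels, canonically ordered.

    The name is a display handle only; equality and hashing look at the
    element collection alone.
    """

    __slots__ = ("name", "elements", "_members")

    def __init__(self, name: str, elements: Iterable[str]):
        elems = tuple(sorted(elements))
        members = frozenset(elems)
        if len(members) != len(elems):
            seen: set[str] = set()
            for e in elems:
                if e in seen:
                    raise ValueError(f"duplicate element {e!r} in set {name!r}")
                seen.add(e)
        self.name = name
        self.elements = elems
        self._members = members

    def __contains__(self, label: str) -> bool:
        return label in self._members

    def __iter__(self) -> Iterator[str]:
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FinSet):
            return NotImplemented
        return self.elements == other.elements

    def __hash__(self) -> int:
        return hash(self.elements)

    def __repr__(self) -> str:
        return f"FinSet({self.name!r}, {{{', '.join(self.elements)}}})"


class FinMap:
    """A total function between two :class:`FinSet` objects."""

    __slots__ = ("name", "dom", "cod", "assignment")

    def __init__(self, name: str, dom: FinSet, cod: FinSet,
                 assignment: Mapping[str, str]):
        missing = [x for x in dom if x not in assignment]
        if missing:
            raise ValueError(
                f"map {name!r} is not total: no value for {missing[0]!r}"
            )
        cleaned: dict[str, str] = {}
        for x in dom:
            y = assignment[x]
            if y not in cod:
                raise ValueError(
                    f"map {name!r} sends {x!r} to {y!r}, "
                    f"not an element of {cod.name!r}"
                )
            cleaned[x] = y
        self.name = name
        self.dom = dom
        self.cod = cod
        self.assignment = cleaned

    def __call__(self, x: str) -> str:
        try:
            return self.assignment[x]
        except KeyError:
            raise ValueError(f"{x!r} not in domain of map {self.name!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FinMap):
            return NotImplemented
        return (self.dom.elements == other.dom.elements
                and self.cod.elements == other.cod.elements
                and self.assignment == other.assignment)

    def __hash__(self) -> int:
        return hash((self.dom.elements, self.cod.elements,
                     tuple(sorted(self.assignment.items()))))

    def __repr__(self) -> str:
        return f"FinMap({self.name!r}: {self.dom.name} -> {self.cod.name})"


def identity(a: FinSet) -> FinMap:
    """The identity morphism on *a*."""
    return FinMap(f"id_{a.name}", a, a, {x: x for x in a})


def compose(g: FinMap, f: FinMap) -> FinMap:
    """The composite ``g after f`` (``x -> g(f(x))``).

    Requires ``cod(f) == dom(g)`` extensionally.
    """
    if f.cod != g.dom:
        raise CompositionError(
            f"cannot compose {g.name!r} after {f.name!r}: codomain "
            f"{{{', '.join(f.cod.elements)}}} != domain "
            f"{{{', '.join(g.dom.elements)}}}"
        )
    return FinMap(f"{g.name}.{f.name}", f.dom, g.cod,
                  {x: g(f(x)) for x in f.dom})


@dataclass(frozen=True)
class IsoReport:
    """Outcome of an isomorphism test: bijectivity plus the inverse."""

    is_iso: bool
    inverse: Optional[FinMap]
    reason: str


def is_isomorphism(f: FinMap) -> IsoReport:
    """Report whether *f* is a bijection, returning the inverse when it is."""
    inverse_assignment: dict[str, str] = {}
    for x in f.dom:
        y = f(x)
        if y in inverse_assignment:
            return IsoReport(False, None,
                             f"not injective: {inverse_assignment[y]!r} and "
                             f"{x!r} both map to {y!r}")
        inverse_assignment[y] = x
    if len(inverse_assignment) != len(f.cod):
        missed = sorted(set(f.cod.elements) - set(inverse_assignment))
        return IsoReport(False, None,
                         f"not surjective: {missed[0]!r} has no preimage")
    inverse = FinMap(f"{f.name}^-1", f.cod, f.dom, inverse_assignment)
    return IsoReport(True, inverse, "bijection")


def enumerate_maps(a: FinSet, b: FinSet,
                   cap: int = DEFAULT_ENUM_CAP) -> list[FinMap]:
    """All total maps ``a -> b`` in canonical lexicographic order.

    There are ``|b| ** |a|`` of them: exactly one when *a* is empty, none
    when *a* is nonempty and *b* is empty.  Raises
    :class:`~catsys.errors.EnumerationCapError` when the count exceeds *cap*.
    """
    count = len(b) ** len(a)
    if count > cap:
        raise EnumerationCapError(count, cap,
                                  what=f"maps {a.name} -> {b.name}")
    out: list[FinMap] = []
    for i, targets in enumerate(itertools.product(b.elements,
                                                  repeat=len(a))):
        out.append(FinMap(f"{a.name}->{b.name}#{i}", a, b,
                          dict(zip(a.elements, targets))))
    return out


def hom_count(a: FinSet, b: FinSet) -> int:
    """``|Hom(a, b)| = |b| ** |a|`` without materializing the maps."""
    return len(b) ** len(a)
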