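"""Functors, natural transformations, and adjunction verification.

The adjunction at the centre of the systematicity account pairs the
diagonal functor Δ (a set A goes to the pair (A, A)) with the product
functor × (a pair (B1, B2) goes to the set of ordered pairs B1xB2).  The
unit is the copying map a -> (a,a) and the counit is the pair of
coordinate projections.  Given candidate functors, a unit and a counit,
:func:`verify_adjunction` checks, by exhaustive enumeration over small
probe objects:

* well-typedness and naturality of unit and counit,
* both triangle identities,
* the universal factorization: for every pair map f = (f1, f2) out of
  Δ(A) there is exactly one h: A -> ×(B) whose composites with the counit
  components recover f1 and f2, and that unique h is the one the
  adjunction itself constructs, ×(f) . η_A.

An architecture whose accessor pair disagrees with its construction (the
"swapped projections" alternative) fails this last consistency check —
that failure, not any defect of the swapped product as a product, is what
singles out the uniform architecture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .core import (DEFAULT_ENUM_CAP, FinMap, FinSet, compose, enumerate_maps,
                   hom_count, identity, split_label, tuple_label)
from .diagrams import default_probes, product_set
from .errors import EnumerationCapError


@dataclass(frozen=True)
class PairObject:
    """An object of the pair category Set x Set."""

    left: FinSet
    right: FinSet


@dataclass(frozen=True)
class PairMap:
    """A morphism of the pair category: two maps acting componentwise."""

    left: FinMap
    right: FinMap

    @property
    def dom(self) -> PairObject:
        return PairObject(self.left.dom, self.right.dom)

    @property
    def cod(self) -> PairObject:
        return PairObject(self.left.cod, self.right.cod)


def pair_identity(p: PairObject) -> PairMap:
    return PairMap(identity(p.left), identity(p.right))


def pair_compose(g: PairMap, f: PairMap) -> PairMap:
    return PairMap(compose(g.left, f.left), compose(g.right, f.right))


@dataclass
class FunctorSpec:
    """A functor given extensionally by its object and morphism actions."""

    name: str
    object_action: Callable
    map_action: Callable

    def __call__(self, x):
        if isinstance(x, (FinSet, PairObject)):
            return self.object_action(x)
        return self.map_action(x)


@dataclass
class NatTransSpec:
    """A natural transformation: one component morphism per object."""

    name: str
    source: FunctorSpec
    target: FunctorSpec
    component: Callable  # object -> FinMap or PairMap


# --------------------------------------------------------------------------
# the diagonal / product adjunction
# --------------------------------------------------------------------------

def diagonal_functor() -> FunctorSpec:
    """Δ: Set -> Set x Set, A -> (A, A) and f -> (f, f)."""
    return FunctorSpec(
        "diagonal",
        lambda a: PairObject(a, a),
        lambda f: PairMap(f, f),
    )


def _product_map(fg: PairMap) -> FinMap:
    """(f, g) -> f x g : the map (a,b) -> (f(a), g(b))."""
    dom = product_set(fg.left.dom, fg.right.dom)
    cod = product_set(fg.left.cod, fg.right.cod)
    assignment = {}
    for e in dom:
        a, b = split_label(e)
        assignment[e] = tuple_label((fg.left(a), fg.right(b)))
    return FinMap(f"{fg.left.name}x{fg.right.name}", dom, cod, assignment)


def product_functor() -> FunctorSpec:
    """×: Set x Set -> Set, (A, B) -> AxB and (f, g) -> f x g."""
    return FunctorSpec(
        "product",
        lambda p: product_set(p.left, p.right),
        _product_map,
    )


def unit_component(a: FinSet) -> FinMap:
    """η_A : A -> AxA, the copying map a -> (a, a)."""
    apex = product_set(a, a)
    return FinMap(f"eta_{a.name}", a, apex,
                  {x: tuple_label((x, x)) for x in a})


def projections(a: FinSet, b: FinSet) -> tuple[FinMap, FinMap]:
    """The coordinate projections of the canonical product AxB."""
    apex = product_set(a, b)
    p1 = FinMap("p1", apex, a, {e: split_label(e)[0] for e in apex})
    p2 = FinMap("p2", apex, b, {e: split_label(e)[1] for e in apex})
    return p1, p2


def counit_component(p: PairObject) -> PairMap:
    """ε_(A,B) : (AxB, AxB) -> (A, B), the projection pair (p1, p2)."""
    p1, p2 = projections(p.left, p.right)
    return PairMap(p1, p2)


def swapped_counit_component(p: PairObject) -> PairMap:
    """The exchanged projection pair (p2, p1).

    Only well-typed when the two components coincide as sets; used as the
    alternative-architecture counterexample.
    """
    p1, p2 = projections(p.left, p.right)
    return PairMap(p2, p1)


def unit_transformation() -> NatTransSpec:
    return NatTransSpec("unit", None, None, unit_component)


def counit_transformation() -> NatTransSpec:
    return NatTransSpec("counit", None, None, counit_component)


# --------------------------------------------------------------------------
# verification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjunctionFinding:
    check: str       # e.g. "unit-naturality", "triangle-right", "factorization"
    location: str    # which probe objects / morphism
    detail: str


@dataclass
class AdjunctionReport:
    ok: bool
    factorizations_tested: int
    findings: list[AdjunctionFinding]

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "factorizations_tested": self.factorizations_tested,
            "findings": [
                {"check": f.check, "location": f.location, "detail": f.detail}
                for f in self.findings
            ],
        }


def _pair_maps(p: PairObject, q: PairObject,
               cap: int) -> list[PairMap]:
    return [PairMap(u, v)
            for u in enumerate_maps(p.left, q.left, cap)
            for v in enumerate_maps(p.right, q.right, cap)]


def verify_adjunction(left: FunctorSpec,
                      right: FunctorSpec,
                      unit: NatTransSpec,
                      counit: Optional[NatTransSpec] = None,
                      probes: Optional[Sequence[FinSet]] = None,
                      cap: int = DEFAULT_ENUM_CAP) -> AdjunctionReport:
    """Exhaustively verify a candidate (left ⊣ right) adjunction.

    *left* maps Set to the pair category and *right* maps back.  Probes
    default to all sets of sizes 0..2 over a two-letter alphabet; pair
    probes are all ordered pairs of probes.
    """
    if counit is None:
        counit = counit_transformation()
    probe_objs = list(probes) if probes is not None else default_probes()
    pair_probes = [PairObject(x, y)
                   for x in probe_objs for y in probe_objs]
    findings: list[AdjunctionFinding] = []
    tested = 0

    def found(check: str, location: str, detail: str) -> None:
        findings.append(AdjunctionFinding(check, location, detail))

    # unit typing + naturality
    for a in probe_objs:
        eta = unit.component(a)
        gfa = right(left(a))
        if eta.dom != a or eta.cod != gfa:
            found("unit-typing", a.name,
                  f"eta_{a.name} is not a map {a.name} -> right(left({a.name}))")
    for a, a2 in itertools.product(probe_objs, repeat=2):
        eta_a, eta_a2 = unit.component(a), unit.component(a2)
        if eta_a.dom != a or eta_a2.dom != a2:
            continue  # typing failure already recorded
        for f in enumerate_maps(a, a2, cap):
            lhs = compose(right(left(f)), eta_a)
            rhs = compose(eta_a2, f)
            if lhs != rhs:
                found("unit-naturality", f"{a.name}->{a2.name}",
                      f"square fails for {f.name}")
                break

    # counit typing + naturality
    for b in pair_probes:
        loc = f"({b.left.name},{b.right.name})"
        eps = counit.component(b)
        ok_typing = (eps.left.dom == right(b) == eps.right.dom
                     and eps.left.cod == b.left
                     and eps.right.cod == b.right)
        if not ok_typing:
            found("counit-typing", loc,
                  "counit component is not a pair map "
                  "left(right(B)) -> B")
    for b, b2 in itertools.product(pair_probes, repeat=2):
        eps_b, eps_b2 = counit.component(b), counit.component(b2)
        if (eps_b.left.cod != b.left or eps_b.right.cod != b.right
                or eps_b2.left.cod != b2.left or eps_b2.right.cod != b2.right):
            continue
        for g in _pair_maps(b, b2, cap):
            lhs = pair_compose(eps_b2, left(right(g)))
            rhs = pair_compose(g, eps_b)
            if (lhs.left, lhs.right) != (rhs.left, rhs.right):
                found("counit-naturality",
                      f"({b.left.name},{b.right.name})->"
                      f"({b2.left.name},{b2.right.name})",
                      "square fails")
                break

    # triangle identities
    for a in probe_objs:
        eta = unit.component(a)
        fa = left(a)
        eps_fa = counit.component(fa)
        if eps_fa.left.cod == fa.left and eps_fa.right.cod == fa.right:
            tri = pair_compose(eps_fa, left(eta))
            ident = pair_identity(fa)
            if (tri.left, tri.right) != (ident.left, ident.right):
                found("triangle-left", a.name,
                      "counit(left A) . left(unit A) != id")
        else:
            found("triangle-left", a.name, "counit ill-typed at left(A)")
    for b in pair_probes:
        loc = f"({b.left.name},{b.right.name})"
        eps = counit.component(b)
        if eps.left.cod != b.left or eps.right.cod != b.right:
            found("triangle-right", loc, "counit ill-typed at B")
            continue
        gb = right(b)
        tri = compose(right(eps), unit.component(gb))
        if tri != identity(gb):
            found("triangle-right", loc,
                  "right(counit B) . unit(right B) != id")

    # universal factorization through the counit, consistent with the unit
    for a in probe_objs:
        fa = left(a)
        for b in pair_probes:
            loc = f"{a.name} -> ({b.left.name},{b.right.name})"
            eps = counit.component(b)
            if eps.left.cod != b.left or eps.right.cod != b.right:
                found("factorization", loc, "counit ill-typed; skipped")
                continue
            gb = right(b)
            candidates = enumerate_maps(a, gb, cap)
            for f in _pair_maps(fa, b, cap):
                tested += 1
                matching = [h for h in candidates
                            if compose(eps.left, h) == f.left
                            and compose(eps.right, h) == f.right]
                if len(matching) != 1:
                    found("factorization", loc,
                          f"{len(matching)} maps factor "
                          f"({f.left.name},{f.right.name}) through the counit")
                    continue
                constructed = compose(right(f), unit.component(a))
                if constructed != matching[0]:
                    found("factorization", loc,
                          "unique factoring map disagrees with "
                          "right(f) . unit: architecture is mixed")
    return AdjunctionReport(not findings, tested, findings)


@dataclass
class HomSetReport:
    pair_side: int      # |Hom(ΔA, (B1, B2))|
    product_side: int   # |Hom(A, B1xB2)|
    bijection: bool

    def to_dict(self) -> dict:
        return {"pair_side": self.pair_side,
                "product_side": self.product_side,
                "bijection": self.bijection}


def hom_set_bijection(a: FinSet, p: PairObject,
                      cap: int = DEFAULT_ENUM_CAP) -> HomSetReport:
    """Check Hom(ΔA, (B1,B2)) ≅ Hom(A, B1xB2) via h -> (p1.h, p2.h)."""
    need = hom_count(a, p.left) * hom_count(a, p.right)
    if need > cap:
        raise EnumerationCapError(need, cap, what="pair-side hom maps")
    apex = product_set(p.left, p.right)
    need_right = hom_count(a, apex)
    if need_right > cap:
        raise EnumerationCapError(need_right, cap, what="product-side hom maps")
    pair_side = [(u, v)
                 for u in enumerate_maps(a, p.left, cap)
                 for v in enumerate_maps(a, p.right, cap)]
    product_side = enumerate_maps(a, apex, cap)
    p1, p2 = projections(p.left, p.right)
    images = [(compose(p1, h), compose(p2, h)) for h in product_side]
    injective = len(set((tuple(sorted(u.assignment.items())),
                         tuple(sorted(v.assignment.items())))
                        for u, v in images)) == len(images)
    surjective = all(any(u == iu and v == iv for iu, iv in images)
                     for u, v in pair_side)
    return HomSetReport(len(pair_side), len(product_side),
                        injective and surjective
                        and len(pair_side) == len(product_side))
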