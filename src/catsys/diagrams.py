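"""Finite diagrams, commutativity checking, and (co)limit constructions.

A :class:`Shape` is a small directed multigraph; a :class:`Diagram`
decorates its nodes with finite sets and its edges with total maps.  The
module builds the canonical universal constructions over such diagrams —
terminal object, product, pullback, equalizer, their duals, and generic
limits/colimits — and, crucially, *verifies* universality by exhaustive
search over small probe apexes: a cone is universal when every cone over
the same diagram factors through it by exactly one mediating morphism.

Quotients (coequalizer, pushout, colimit) label each equivalence class by
its lexicographically least member, so class labels are themselves plain
element labels and the constructions stay composable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import (DEFAULT_ENUM_CAP, FinMap, FinSet, compose, enumerate_maps,
                   identity, split_label, tuple_label)
from .errors import (CodomainMismatchError, DiagramError, DomainMismatchError,
                     EnumerationCapError, NoFactorizationError,
                     NotParallelError, ShapeError)

#: Default bound on path length during commutativity checking; covers every
#: diagram arising from the constructions in this package with margin.
DEFAULT_MAX_PATH_LEN = 8


# --------------------------------------------------------------------------
# shapes and diagrams
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Shape:
    """A finite directed multigraph: labelled nodes and labelled edges."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (label, source, target)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ShapeError("node labels must be distinct")
        labels = [e[0] for e in self.edges]
        if len(set(labels)) != len(labels):
            raise ShapeError("edge labels must be distinct")
        for label, src, tgt in self.edges:
            if src not in self.nodes or tgt not in self.nodes:
                raise ShapeError(
                    f"edge {label!r} joins undeclared node "
                    f"({src!r} -> {tgt!r})")

    def out_edges(self, node: str) -> list[tuple[str, str, str]]:
        return [e for e in self.edges if e[1] == node]

    def is_acyclic(self) -> bool:
        adjacency: dict[str, list[str]] = {n: [] for n in self.nodes}
        for _, src, tgt in self.edges:
            adjacency[src].append(tgt)
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(n: str) -> bool:
            if state.get(n) == 0:
                return False
            if state.get(n) == 1:
                return True
            state[n] = 0
            ok = all(visit(m) for m in adjacency[n])
            state[n] = 1
            return ok

        return all(visit(n) for n in self.nodes)


def empty_shape() -> Shape:
    return Shape((), ())


def discrete_shape(nodes: Sequence[str]) -> Shape:
    return Shape(tuple(nodes), ())


def sink_shape() -> Shape:
    """Two outer objects mapping into a shared inner one: A -> C <- B."""
    return Shape(("A", "B", "C"), (("f", "A", "C"), ("g", "B", "C")))


def parallel_shape() -> Shape:
    """A parallel pair A => B (equalizer/coequalizer shape)."""
    return Shape(("A", "B"), (("u", "A", "B"), ("v", "A", "B")))


def span_shape() -> Shape:
    """One object mapping into two others: B <- A -> C (pushout shape)."""
    return Shape(("A", "B", "C"), (("f", "A", "B"), ("g", "A", "C")))


@dataclass(frozen=True)
class Diagram:
    """Finite sets on the nodes and total maps on the edges of a shape."""

    shape: Shape
    objects: Mapping[str, FinSet]
    maps: Mapping[str, FinMap]

    def __post_init__(self):
        for n in self.shape.nodes:
            if n not in self.objects:
                raise DiagramError(f"node {n!r} has no object")
        for label, src, tgt in self.shape.edges:
            if label not in self.maps:
                raise DiagramError(f"edge {label!r} has no map")
            m = self.maps[label]
            if m.dom != self.objects[src]:
                raise DiagramError(
                    f"edge {label!r}: map domain disagrees with node {src!r}")
            if m.cod != self.objects[tgt]:
                raise DiagramError(
                    f"edge {label!r}: map codomain disagrees with node {tgt!r}")


@dataclass
class Cone:
    """An apex with one commuting leg into every node object of a diagram."""

    apex: FinSet
    legs: dict[str, FinMap]  # node -> apex -> object
    diagram: Diagram

    def violations(self) -> list[str]:
        """Reasons this fails to be a cone (empty list when it is one)."""
        out = []
        for n in self.diagram.shape.nodes:
            leg = self.legs.get(n)
            if leg is None:
                out.append(f"missing leg at node {n!r}")
                continue
            if leg.dom != self.apex or leg.cod != self.diagram.objects[n]:
                out.append(f"leg at node {n!r} has wrong endpoints")
        if out:
            return out
        for label, src, tgt in self.diagram.shape.edges:
            if compose(self.diagram.maps[label], self.legs[src]) != self.legs[tgt]:
                out.append(f"edge {label!r} does not commute with the legs")
        return out


@dataclass
class Cocone:
    """Dual of :class:`Cone`: legs from the node objects into the apex."""

    apex: FinSet
    legs: dict[str, FinMap]  # node -> object -> apex
    diagram: Diagram
    classes: Optional[dict[str, tuple[str, ...]]] = None  # quotient classes

    def violations(self) -> list[str]:
        out = []
        for n in self.diagram.shape.nodes:
            leg = self.legs.get(n)
            if leg is None:
                out.append(f"missing leg at node {n!r}")
                continue
            if leg.dom != self.diagram.objects[n] or leg.cod != self.apex:
                out.append(f"leg at node {n!r} has wrong endpoints")
        if out:
            return out
        for label, src, tgt in self.diagram.shape.edges:
            if compose(self.legs[tgt], self.diagram.maps[label]) != self.legs[src]:
                out.append(f"edge {label!r} does not commute with the legs")
        return out


# --------------------------------------------------------------------------
# commutativity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PathPairFailure:
    source: str
    target: str
    path_a: tuple[str, ...]
    path_b: tuple[str, ...]
    witness: str
    value_a: str
    value_b: str


@dataclass
class CommutativityReport:
    ok: bool
    pairs_checked: int
    failures: list[PathPairFailure]

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "pairs_checked": self.pairs_checked,
            "failures": [
                {"source": f.source, "target": f.target,
                 "path_a": list(f.path_a), "path_b": list(f.path_b),
                 "witness": f.witness,
                 "value_a": f.value_a, "value_b": f.value_b}
                for f in self.failures
            ],
        }


def _all_paths(shape: Shape, max_len: int) -> dict[tuple[str, str],
                                                   list[tuple[str, ...]]]:
    """Every edge-path of length 1..max_len, keyed by (source, target)."""
    paths: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    for start in shape.nodes:
        frontier = [(start, ())]
        for _ in range(max_len):
            nxt = []
            for at, trail in frontier:
                for label, _, tgt in shape.out_edges(at):
                    new_trail = trail + (label,)
                    paths.setdefault((start, tgt), []).append(new_trail)
                    nxt.append((tgt, new_trail))
            frontier = nxt
            if not frontier:
                break
    return paths


def _composite(d: Diagram, source: str, path: Sequence[str]) -> FinMap:
    m = identity(d.objects[source])
    for label in path:
        m = compose(d.maps[label], m)
    return m


def check_commutative(d: Diagram,
                      max_path_len: Optional[int] = DEFAULT_MAX_PATH_LEN
                      ) -> CommutativityReport:
    """Check that all parallel path pairs (one of length > 1) agree.

    With ``max_path_len=None`` the shape must be acyclic, and the bound
    defaults to the number of edges (the longest possible simple path).
    """
    if max_path_len is None:
        if not d.shape.is_acyclic():
            raise ShapeError(
                "cyclic shape requires a finite max_path_len bound")
        max_path_len = max(1, len(d.shape.edges))
    paths = _all_paths(d.shape, max_path_len)
    failures: list[PathPairFailure] = []
    pairs_checked = 0
    for (src, tgt), plist in sorted(paths.items()):
        composites = [(p, _composite(d, src, p)) for p in plist]
        for (pa, ma), (pb, mb) in itertools.combinations(composites, 2):
            if len(pa) <= 1 and len(pb) <= 1:
                continue
            pairs_checked += 1
            if ma != mb:
                witness = next(x for x in d.objects[src]
                               if ma(x) != mb(x))
                failures.append(PathPairFailure(
                    src, tgt, pa, pb, witness, ma(witness), mb(witness)))
    return CommutativityReport(not failures, pairs_checked, failures)


# --------------------------------------------------------------------------
# canonical constructions
# --------------------------------------------------------------------------

def product_set(a: FinSet, b: FinSet) -> FinSet:
    """The set of pair labels ``(x,y)`` for x in a, y in b."""
    return FinSet(f"{a.name}x{b.name}",
                  (tuple_label((x, y)) for x in a for y in b))


def product(a: FinSet, b: FinSet) -> Cone:
    """The Cartesian product with its coordinate projections.

    Returned as a cone over the discrete two-node shape (nodes A, B).
    """
    apex = product_set(a, b)
    d = Diagram(discrete_shape(("A", "B")), {"A": a, "B": b}, {})
    p1 = FinMap("p1", apex, a, {e: split_label(e)[0] for e in apex})
    p2 = FinMap("p2", apex, b, {e: split_label(e)[1] for e in apex})
    return Cone(apex, {"A": p1, "B": p2}, d)


def pullback(f: FinMap, g: FinMap) -> Cone:
    """The constrained product of dom(f) and dom(g) over their common codomain.

    Apex elements are the pairs ``(a,b)`` with ``f(a) == g(b)``; the cone
    lives over the sink shape A -> C <- B.
    """
    if f.cod != g.cod:
        raise CodomainMismatchError(
            f"pullback needs a common codomain; {f.name!r} ends in "
            f"{{{', '.join(f.cod.elements)}}} but {g.name!r} ends in "
            f"{{{', '.join(g.cod.elements)}}}")
    d = Diagram(sink_shape(),
                {"A": f.dom, "B": g.dom, "C": f.cod},
                {"f": f, "g": g})
    elems = [tuple_label((a, b)) for a in f.dom for b in g.dom
             if f(a) == g(b)]
    apex = FinSet(f"pb({f.name},{g.name})", elems)
    p1 = FinMap("p1", apex, f.dom, {e: split_label(e)[0] for e in apex})
    p2 = FinMap("p2", apex, g.dom, {e: split_label(e)[1] for e in apex})
    return Cone(apex, {"A": p1, "B": p2, "C": compose(f, p1)}, d)


def equalizer(f: FinMap, g: FinMap) -> Cone:
    """The subset of the common domain where the parallel pair agrees."""
    if f.dom != g.dom or f.cod != g.cod:
        raise NotParallelError(
            f"equalizer needs a parallel pair; {f.name!r} and {g.name!r} "
            "have different endpoints")
    d = Diagram(parallel_shape(), {"A": f.dom, "B": f.cod},
                {"u": f, "v": g})
    apex = FinSet(f"eq({f.name},{g.name})",
                  (x for x in f.dom if f(x) == g(x)))
    incl = FinMap("incl", apex, f.dom, {x: x for x in apex})
    return Cone(apex, {"A": incl, "B": compose(f, incl)}, d)


class _UnionFind:
    """Small deterministic union-find used for quotient constructions."""

    def __init__(self, elements: Iterable[str]):
        self.parent = {e: e for e in elements}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            # keep the lexicographically smaller representative
            if ry < rx:
                rx, ry = ry, rx
            self.parent[ry] = rx

    def classes(self) -> dict[str, tuple[str, ...]]:
        grouped: dict[str, list[str]] = {}
        for e in self.parent:
            grouped.setdefault(self.find(e), []).append(e)
        return {rep: tuple(sorted(members))
                for rep, members in grouped.items()}


def _quotient(elements: Iterable[str],
              identify: Iterable[tuple[str, str]]
              ) -> tuple[dict[str, tuple[str, ...]], dict[str, str]]:
    """Quotient a label set by the equivalence generated by `identify`.

    Returns (classes keyed by least member, element -> class label).
    """
    uf = _UnionFind(elements)
    for x, y in identify:
        uf.union(x, y)
    classes = uf.classes()
    rep_of = {e: uf.find(e) for e in uf.parent}
    return classes, rep_of


def coproduct(a: FinSet, b: FinSet) -> Cocone:
    """The tagged disjoint union ``(l,x)`` / ``(r,y)`` with its injections."""
    d = Diagram(discrete_shape(("A", "B")), {"A": a, "B": b}, {})
    apex = FinSet(f"{a.name}+{b.name}",
                  itertools.chain((tuple_label(("l", x)) for x in a),
                                  (tuple_label(("r", y)) for y in b)))
    inl = FinMap("inl", a, apex, {x: tuple_label(("l", x)) for x in a})
    inr = FinMap("inr", b, apex, {y: tuple_label(("r", y)) for y in b})
    return Cocone(apex, {"A": inl, "B": inr}, d)


def coequalizer(f: FinMap, g: FinMap) -> Cocone:
    """Quotient of the common codomain by the equivalence f(x) ~ g(x).

    Class labels are the lexicographically least members, so the apex is a
    plain label set; the cocone records the full classes as well.
    """
    if f.dom != g.dom or f.cod != g.cod:
        raise NotParallelError(
            f"coequalizer needs a parallel pair; {f.name!r} and {g.name!r} "
            "have different endpoints")
    d = Diagram(parallel_shape(), {"A": f.dom, "B": f.cod},
                {"u": f, "v": g})
    classes, rep_of = _quotient(f.cod, ((f(x), g(x)) for x in f.dom))
    apex = FinSet(f"coeq({f.name},{g.name})", classes.keys())
    q = FinMap("q", f.cod, apex, rep_of)
    return Cocone(apex, {"A": compose(q, f), "B": q}, d, classes=classes)


def pushout(f: FinMap, g: FinMap) -> Cocone:
    """Quotient of the tagged disjoint union of the codomains by f(z) ~ g(z)."""
    if f.dom != g.dom:
        raise DomainMismatchError(
            f"pushout needs a common domain; {f.name!r} starts at "
            f"{{{', '.join(f.dom.elements)}}} but {g.name!r} starts at "
            f"{{{', '.join(g.dom.elements)}}}")
    d = Diagram(span_shape(), {"A": f.dom, "B": f.cod, "C": g.cod},
                {"f": f, "g": g})
    union = ([tuple_label(("l", x)) for x in f.cod]
             + [tuple_label(("r", y)) for y in g.cod])
    classes, rep_of = _quotient(
        union,
        ((tuple_label(("l", f(z))), tuple_label(("r", g(z)))) for z in f.dom))
    apex = FinSet(f"po({f.name},{g.name})", classes.keys())
    leg_b = FinMap("q_l", f.cod, apex,
                   {x: rep_of[tuple_label(("l", x))] for x in f.cod})
    leg_c = FinMap("q_r", g.cod, apex,
                   {y: rep_of[tuple_label(("r", y))] for y in g.cod})
    return Cocone(apex, {"A": compose(leg_b, f), "B": leg_b, "C": leg_c},
                  d, classes=classes)


def limit(d: Diagram, cap: int = DEFAULT_ENUM_CAP) -> Cone:
    """The canonical limit: matching families encoded as node-order tuples.

    Apex elements are tuples over the lexicographically sorted node labels
    whose coordinates are compatible with every edge map.  The empty shape
    yields the terminal singleton ``{()}``.
    """
    nodes = sorted(d.shape.nodes)
    total = math.prod(len(d.objects[n]) for n in nodes)
    if total > cap:
        raise EnumerationCapError(total, cap, what="limit tuples")
    elems = []
    legs_assign: dict[str, dict[str, str]] = {n: {} for n in nodes}
    for values in itertools.product(*(d.objects[n].elements for n in nodes)):
        at = dict(zip(nodes, values))
        if all(d.maps[label](at[src]) == at[tgt]
               for label, src, tgt in d.shape.edges):
            label = tuple_label(values)
            elems.append(label)
            for n, v in zip(nodes, values):
                legs_assign[n][label] = v
    apex = FinSet("lim", elems)
    legs = {n: FinMap(f"proj_{n}", apex, d.objects[n], legs_assign[n])
            for n in nodes}
    return Cone(apex, legs, d)


def terminal() -> Cone:
    """The terminal object: the limit of the empty diagram (a singleton)."""
    return limit(Diagram(empty_shape(), {}, {}))


def colimit(d: Diagram) -> Cocone:
    """The canonical colimit: tagged disjoint union modulo edge identification."""
    nodes = sorted(d.shape.nodes)
    union = [tuple_label((n, x)) for n in nodes for x in d.objects[n]]
    pairs = [(tuple_label((src, x)), tuple_label((tgt, d.maps[label](x))))
             for label, src, tgt in d.shape.edges
             for x in d.objects[src]]
    classes, rep_of = _quotient(union, pairs)
    apex = FinSet("colim", classes.keys())
    legs = {n: FinMap(f"inj_{n}", d.objects[n], apex,
                      {x: rep_of[tuple_label((n, x))] for x in d.objects[n]})
            for n in nodes}
    return Cocone(apex, legs, d, classes=classes)


# --------------------------------------------------------------------------
# mediating morphisms and universality
# --------------------------------------------------------------------------

def mediating_morphism(c: Cone, u: Cone) -> FinMap:
    """The unique map from c's apex to u's apex commuting with all legs.

    *u* must be a limit cone (each leg-value signature realized by exactly
    one apex element); *c* must genuinely be a cone, else
    :class:`~catsys.errors.NoFactorizationError` is raised.
    """
    if c.diagram.shape != u.diagram.shape:
        raise NoFactorizationError("cones live over different shapes")
    bad = c.violations()
    if bad:
        raise NoFactorizationError(
            f"not a cone, cannot factor: {bad[0]}")
    nodes = sorted(u.diagram.shape.nodes)
    by_signature: dict[tuple[str, ...], list[str]] = {}
    for y in u.apex:
        sig = tuple(u.legs[n](y) for n in nodes)
        by_signature.setdefault(sig, []).append(y)
    assignment = {}
    for x in c.apex:
        sig = tuple(c.legs[n](x) for n in nodes)
        candidates = by_signature.get(sig, [])
        if len(candidates) == 0:
            raise NoFactorizationError(
                f"no apex element of the target cone matches the legs "
                f"of {x!r}")
        if len(candidates) > 1:
            raise NoFactorizationError(
                f"target cone is not a limit: {x!r} factors through "
                f"{len(candidates)} elements")
        assignment[x] = candidates[0]
    return FinMap(f"u_{c.apex.name}", c.apex, u.apex, assignment)


def default_probes() -> list[FinSet]:
    """Probe apexes of sizes 0, 1, 2 over a fixed two-letter alphabet."""
    return [FinSet("probe0", ()),
            FinSet("probe1", ("p",)),
            FinSet("probe2", ("p", "q"))]


def enumerate_cones(d: Diagram, apex: FinSet,
                    cap: int = DEFAULT_ENUM_CAP) -> list[Cone]:
    """Every cone over *d* with the given apex, by exhaustive leg search."""
    nodes = sorted(d.shape.nodes)
    total = math.prod(len(d.objects[n]) ** len(apex) for n in nodes)
    if total > cap:
        raise EnumerationCapError(total, cap, what="candidate leg families")
    leg_choices = [enumerate_maps(apex, d.objects[n], cap) for n in nodes]
    cones = []
    for combo in itertools.product(*leg_choices):
        legs = dict(zip(nodes, combo))
        if all(all(d.maps[label](legs[src](x)) == legs[tgt](x)
                   for x in apex)
               for label, src, tgt in d.shape.edges):
            cones.append(Cone(apex, legs, d))
    return cones


@dataclass(frozen=True)
class UniversalFailure:
    probe: str
    cone_signature: tuple[tuple[str, ...], ...]  # per apex element, leg values
    factorizations: int


@dataclass
class UniversalReport:
    ok: bool
    cones_tested: int
    failures: list[UniversalFailure]

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "cones_tested": self.cones_tested,
            "failures": [
                {"probe": f.probe,
                 "cone_signature": [list(s) for s in f.cone_signature],
                 "factorizations": f.factorizations}
                for f in self.failures
            ],
        }


def verify_universal(u: Cone,
                     d: Optional[Diagram] = None,
                     probe_apexes: Optional[Sequence[FinSet]] = None,
                     cap: int = DEFAULT_ENUM_CAP) -> UniversalReport:
    """Test the universal property of *u* by exhaustive probing.

    For every probe apex X and every cone over the diagram with apex X,
    count the mediating maps into *u*; universality demands exactly one.
    The count of maps ``m`` with ``legs(u) . m == legs(cone)`` factors over
    elements of X (each x constrains m(x) independently), which is what is
    computed; it equals the count a literal enumeration of Hom(X, apex(u))
    would find.
    """
    if d is None:
        d = u.diagram
    nodes = sorted(d.shape.nodes)
    probes = list(default_probes())
    if probe_apexes:
        probes.extend(probe_apexes)
    by_signature: dict[tuple[str, ...], int] = {}
    for y in u.apex:
        sig = tuple(u.legs[n](y) for n in nodes)
        by_signature[sig] = by_signature.get(sig, 0) + 1
    failures: list[UniversalFailure] = []
    cones_tested = 0
    for probe in probes:
        for cone in enumerate_cones(d, probe, cap):
            cones_tested += 1
            count = 1
            for x in probe:
                sig = tuple(cone.legs[n](x) for n in nodes)
                count *= by_signature.get(sig, 0)
            if count != 1:
                signature = tuple(
                    tuple(cone.legs[n](x) for n in nodes) for x in probe)
                failures.append(
                    UniversalFailure(probe.name, signature, count))
    return UniversalReport(not failures, cones_tested, failures)
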