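"""Cognitive-domain layer: realize relations as pullbacks and audit them.

A :class:`DomainSpec` names finite sets, maps between them and a
construction *style*; :func:`realize` turns it into a
:class:`RealizedRelation` — an apex of licensed instances with one
projection per role and a witness diagram that must commute.  Five styles
cover the constructions in scope:

``product``
    the full Cartesian product (no constraint; fully systematic domains
    such as the *loves* propositions);
``shared_constraint``
    the pullback of two attribute maps into a common constraint object
    (*parent* over species, subject-verb agreement over number,
    verb-preposition selection over preposition requirement);
``refined_triple``
    a pullback of two pair-sets sharing their constraint coordinate, whose
    apex elements are triples with the constraint in the middle (the
    extended *parent* relation with *whale*/*calf*, the *sheep* fixture);
``characteristic``
    an arbitrary relation recovered as the pullback of its characteristic
    map into a two-element truth object along the inclusion of ``true``
    (the *square* and *less-than* windows) — the subobject-classifier
    pattern;
``quotient``
    the kernel-pair coequalizer of a classifier map (the *absolute*
    relation identifying n with -n).

:func:`audit` operationalizes systematicity: an architecture (a choice of
accessor pair per instance) passes exactly when every instance's accessors
agree with the canonical projections, i.e. everything factors through one
mediating construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from .core import FinMap, FinSet, compose, split_label, tuple_label
from .diagrams import (Cocone, Cone, Diagram, Shape, check_commutative,
                       coequalizer, product, pullback)
from .errors import (MalformedSpecError, SelectorError, UnknownComponentError,
                     WrongStyleError)

STYLES = ("product", "shared_constraint", "refined_triple",
          "characteristic", "quotient")

#: wiring slots each style requires (slot -> "set" or "map")
_WIRING = {
    "product": {"left": "set", "right": "set"},
    "shared_constraint": {"left": "set", "right": "set", "constraint": "set",
                          "left_map": "map", "right_map": "map"},
    "refined_triple": {"left_pairs": "set", "right_pairs": "set",
                       "constraint": "set",
                       "left_map": "map", "right_map": "map"},
    "characteristic": {"left": "set", "right": "set"},
    "quotient": {"base": "set", "classifier": "map"},
}


@dataclass(frozen=True)
class DomainSpec:
    """A structured description of one cognitive domain.

    ``wiring`` binds the style's slots (left/right/constraint/...) to names
    in ``sets``/``maps``; ``roles`` names the projections by the side they
    read (left, right or constraint).
    """

    name: str
    style: str
    sets: Mapping[str, FinSet]
    maps: Mapping[str, FinMap]
    roles: Mapping[str, str]
    wiring: Mapping[str, str]
    relation: Optional[tuple[tuple[str, str], ...]] = None

    def set_for(self, slot: str) -> FinSet:
        return self.sets[self.wiring[slot]]

    def map_for(self, slot: str) -> FinMap:
        return self.maps[self.wiring[slot]]

    def roles_by_side(self) -> dict[str, str]:
        """side -> role name (each side used at most once)."""
        out: dict[str, str] = {}
        for role, side in self.roles.items():
            out[side] = role
        return out

    def validate(self) -> None:
        """Raise :class:`MalformedSpecError` naming the violated requirement."""
        if self.style not in STYLES:
            raise MalformedSpecError(
                f"unknown style {self.style!r}; expected one of {STYLES}")
        needed = _WIRING[self.style]
        for slot, kind in needed.items():
            if slot not in self.wiring:
                raise MalformedSpecError(
                    f"style {self.style!r} requires wiring slot {slot!r}")
            name = self.wiring[slot]
            pool = self.sets if kind == "set" else self.maps
            if name not in pool:
                raise MalformedSpecError(
                    f"wiring slot {slot!r} references undeclared "
                    f"{kind} {name!r}")
        for role, side in self.roles.items():
            if side not in ("left", "right", "constraint"):
                raise MalformedSpecError(
                    f"role {role!r} has unknown side {side!r}")
        sides = [s for s in self.roles.values()]
        if len(sides) != len(set(sides)):
            raise MalformedSpecError("each side may carry at most one role")
        if self.style in ("product", "shared_constraint", "refined_triple",
                          "characteristic"):
            by_side = self.roles_by_side()
            for side in ("left", "right"):
                if side not in by_side:
                    raise MalformedSpecError(
                        f"style {self.style!r} requires a role on the "
                        f"{side} side")
        if self.style == "shared_constraint":
            lm, rm = self.map_for("left_map"), self.map_for("right_map")
            if lm.dom != self.set_for("left"):
                raise MalformedSpecError(
                    "left attribute map must start at the left set")
            if rm.dom != self.set_for("right"):
                raise MalformedSpecError(
                    "right attribute map must start at the right set")
            if lm.cod != self.set_for("constraint") or \
                    rm.cod != self.set_for("constraint"):
                raise MalformedSpecError(
                    "both attribute maps must end in the constraint set")
        if self.style == "refined_triple":
            lp, rp = self.set_for("left_pairs"), self.set_for("right_pairs")
            c = self.set_for("constraint")
            lm, rm = self.map_for("left_map"), self.map_for("right_map")
            for e in lp:
                parts = _components(e)
                if len(parts) != 2:
                    raise MalformedSpecError(
                        f"left pair-set element {e!r} is not a pair")
            for e in rp:
                parts = _components(e)
                if len(parts) != 2:
                    raise MalformedSpecError(
                        f"right pair-set element {e!r} is not a pair")
            if lm.dom != lp or lm.cod != c or \
                    any(lm(e) != _components(e)[1] for e in lp):
                raise MalformedSpecError(
                    "left map must project the second (constraint) "
                    "coordinate of the left pair-set")
            if rm.dom != rp or rm.cod != c or \
                    any(rm(e) != _components(e)[0] for e in rp):
                raise MalformedSpecError(
                    "right map must project the first (constraint) "
                    "coordinate of the right pair-set")
        if self.style == "characteristic":
            if not self.relation:
                raise MalformedSpecError(
                    "characteristic style requires an explicit relation list")
            left, right = self.set_for("left"), self.set_for("right")
            for a, b in self.relation:
                if a not in left:
                    raise MalformedSpecError(
                        f"relation element {a!r} is not in the left set")
                if b not in right:
                    raise MalformedSpecError(
                        f"relation element {b!r} is not in the right set")
        if self.style == "quotient":
            cl = self.map_for("classifier")
            if cl.dom != self.set_for("base"):
                raise MalformedSpecError(
                    "classifier must be total on the base set")


def _components(label: str) -> tuple[str, ...]:
    try:
        return split_label(label)
    except ValueError:
        return (label,)


@dataclass
class QuotientStructure:
    """Fibers of a classifier, realized as a kernel-pair coequalizer."""

    base: FinSet
    classifier: FinMap
    classes: dict[str, tuple[str, ...]]  # class label -> members
    quotient: FinSet
    class_of: FinMap                     # base -> quotient


@dataclass
class RealizedRelation:
    """A domain spec together with its constructed, verified apex."""

    spec: DomainSpec
    apex: FinSet
    projections: dict[str, FinMap]       # role -> apex -> value set
    witness: Diagram
    cone: Optional[Cone] = None          # pullback/product cone (None: quotient)
    quotient: Optional[QuotientStructure] = None
    # label pools used to classify membership failures
    side_pools: dict[str, frozenset] = field(default_factory=dict)

    @property
    def style(self) -> str:
        return self.spec.style


def quotient(base: FinSet, classifier: FinMap) -> QuotientStructure:
    """Group *base* into classifier fibers via the kernel-pair coequalizer."""
    kp = pullback(classifier, classifier)
    coc = coequalizer(kp.legs["A"], kp.legs["B"])
    class_of = coc.legs["B"]
    return QuotientStructure(base, classifier, dict(coc.classes),
                             coc.apex, class_of)


def _relabel_cone(cone: Cone, rename: Mapping[str, str],
                  apex_name: str) -> Cone:
    """Rename a cone's apex elements, rewriting all legs accordingly."""
    apex = FinSet(apex_name, rename.values())
    legs = {}
    for node, leg in cone.legs.items():
        legs[node] = FinMap(leg.name, apex, leg.cod,
                            {rename[x]: leg(x) for x in leg.dom})
    return Cone(apex, legs, cone.diagram)


def realize(spec: DomainSpec) -> RealizedRelation:
    """Construct the relation the spec describes, with verified witness."""
    spec.validate()
    by_side = spec.roles_by_side()
    style = spec.style

    if style == "product":
        left, right = spec.set_for("left"), spec.set_for("right")
        cone = product(left, right)
        apex = FinSet(spec.name, cone.apex.elements)
        cone = _relabel_cone(cone, {e: e for e in cone.apex}, spec.name)
        projections = {by_side["left"]: cone.legs["A"],
                       by_side["right"]: cone.legs["B"]}
        shape = Shape(("A", "B", "P"),
                      (("p1", "P", "A"), ("p2", "P", "B")))
        witness = Diagram(shape, {"P": apex, "A": left, "B": right},
                          {"p1": cone.legs["A"], "p2": cone.legs["B"]})
        pools = {"left": frozenset(left), "right": frozenset(right)}
        return RealizedRelation(spec, apex, projections, witness, cone,
                                side_pools=pools)

    if style == "shared_constraint":
        lm, rm = spec.map_for("left_map"), spec.map_for("right_map")
        raw = pullback(lm, rm)
        cone = _relabel_cone(raw, {e: e for e in raw.apex}, spec.name)
        apex = cone.apex
        projections = {by_side["left"]: cone.legs["A"],
                       by_side["right"]: cone.legs["B"]}
        if "constraint" in by_side:
            projections[by_side["constraint"]] = cone.legs["C"]
        shape = Shape(("A", "B", "C", "P"),
                      (("p1", "P", "A"), ("p2", "P", "B"),
                       ("f", "A", "C"), ("g", "B", "C")))
        witness = Diagram(shape,
                          {"P": apex, "A": lm.dom, "B": rm.dom, "C": lm.cod},
                          {"p1": cone.legs["A"], "p2": cone.legs["B"],
                           "f": lm, "g": rm})
        pools = {"left": frozenset(lm.dom), "right": frozenset(rm.dom)}
        return RealizedRelation(spec, apex, projections, witness, cone,
                                side_pools=pools)

    if style == "refined_triple":
        lm, rm = spec.map_for("left_map"), spec.map_for("right_map")
        raw = pullback(lm, rm)
        rename = {}
        for e in raw.apex:
            left_pair, right_pair = split_label(e)
            a, s = split_label(left_pair)
            s2, b = split_label(right_pair)
            rename[e] = tuple_label((a, s, b))
        cone = _relabel_cone(raw, rename, spec.name)
        apex = cone.apex
        proj = {}
        proj[by_side["left"]] = FinMap(
            "left", apex, FinSet("left_components",
                                 {split_label(e)[0] for e in apex}),
            {e: split_label(e)[0] for e in apex})
        proj[by_side["right"]] = FinMap(
            "right", apex, FinSet("right_components",
                                  {split_label(e)[2] for e in apex}),
            {e: split_label(e)[2] for e in apex})
        if "constraint" in by_side:
            proj[by_side["constraint"]] = compose(lm, cone.legs["A"])
        shape = Shape(("A", "B", "C", "P"),
                      (("p1", "P", "A"), ("p2", "P", "B"),
                       ("f", "A", "C"), ("g", "B", "C")))
        witness = Diagram(shape,
                          {"P": apex, "A": lm.dom, "B": rm.dom, "C": lm.cod},
                          {"p1": cone.legs["A"], "p2": cone.legs["B"],
                           "f": lm, "g": rm})
        pools = {"left": frozenset(split_label(e)[0] for e in lm.dom),
                 "right": frozenset(split_label(e)[1] for e in rm.dom),
                 "constraint": frozenset(lm.cod)}
        return RealizedRelation(spec, apex, proj, witness, cone,
                                side_pools=pools)

    if style == "characteristic":
        left, right = spec.set_for("left"), spec.set_for("right")
        members = {tuple_label(pair) for pair in spec.relation}
        full = product(left, right).apex
        omega = FinSet("Omega", ("false", "true"))
        one = FinSet("1", ("*",))
        chi = FinMap("chi", full, omega,
                     {e: "true" if e in members else "false" for e in full})
        t = FinMap("true", one, omega, {"*": "true"})
        raw = pullback(chi, t)
        rename = {e: split_label(e)[0] for e in raw.apex}
        cone = _relabel_cone(raw, rename, spec.name)
        apex = cone.apex
        p1 = FinMap("p1", apex, left,
                    {e: split_label(e)[0] for e in apex})
        p2 = FinMap("p2", apex, right,
                    {e: split_label(e)[1] for e in apex})
        projections = {by_side["left"]: p1, by_side["right"]: p2}
        shape = Shape(("One", "Omega", "P", "X"),
                      (("incl", "P", "X"), ("bang", "P", "One"),
                       ("chi", "X", "Omega"), ("true", "One", "Omega")))
        witness = Diagram(shape,
                          {"P": apex, "X": full, "One": one, "Omega": omega},
                          {"incl": cone.legs["A"], "bang": cone.legs["B"],
                           "chi": chi, "true": t})
        pools = {"left": frozenset(left), "right": frozenset(right)}
        return RealizedRelation(spec, apex, projections, witness, cone,
                                side_pools=pools)

    # style == "quotient"
    base, classifier = spec.set_for("base"), spec.map_for("classifier")
    q = quotient(base, classifier)
    kp = pullback(classifier, classifier)
    shape = Shape(("B", "K", "Q"),
                  (("k1", "K", "B"), ("k2", "K", "B"), ("q", "B", "Q")))
    witness = Diagram(shape,
                      {"K": kp.apex, "B": base, "Q": q.quotient},
                      {"k1": kp.legs["A"], "k2": kp.legs["B"],
                       "q": q.class_of})
    apex = FinSet(spec.name, q.quotient.elements)
    return RealizedRelation(spec, apex, {}, witness, None, quotient=q,
                            side_pools={"base": frozenset(base)})


# --------------------------------------------------------------------------
# inference, membership, audit
# --------------------------------------------------------------------------

def infer(r: RealizedRelation, role: str,
          selector: Mapping[str, str]) -> str:
    """Project *role* out of the unique apex element matching *selector*.

    The selector is a mapping of role names to required values; it must
    match exactly one apex element.
    """
    if role not in r.projections:
        raise WrongStyleError(
            f"relation {r.spec.name!r} has no role {role!r}")
    for sel_role in selector:
        if sel_role not in r.projections:
            raise SelectorError(f"unknown selector role {sel_role!r}")
    matches = [e for e in r.apex
               if all(r.projections[sr](e) == v
                      for sr, v in selector.items())]
    if not matches:
        raise SelectorError(f"selector {dict(selector)!r} matches no instance")
    if len(matches) > 1:
        raise SelectorError(
            f"selector {dict(selector)!r} is ambiguous: "
            f"{len(matches)} instances match")
    return r.projections[role](matches[0])


@dataclass(frozen=True)
class MembershipResult:
    member: bool
    reason: Optional[str]          # None | "role-set" | "constraint"
    detail: str

    def __bool__(self) -> bool:
        return self.member


def membership(r: RealizedRelation,
               candidate: Union[str, Sequence[str]]) -> MembershipResult:
    """Decide whether *candidate* is a licensed instance, with a reason.

    Non-members are classified either as role-set violations (a component
    sits on the wrong side) or constraint violations (both components on
    the right sides, but their attributes disagree).  Components drawn
    from no declared set raise
    :class:`~catsys.errors.UnknownComponentError`.  For the triple style a
    two-component candidate asks whether *some* constraint value licenses
    the pair.
    """
    if r.style == "quotient":
        raise WrongStyleError("membership is defined for relation styles, "
                              "not quotients")
    if isinstance(candidate, str):
        comps = _components(candidate)
    else:
        comps = tuple(candidate)
    left_pool = r.side_pools["left"]
    right_pool = r.side_pools["right"]
    known = left_pool | right_pool | r.side_pools.get("constraint", frozenset())
    for c in comps:
        if c not in known:
            raise UnknownComponentError(
                f"{c!r} is not an element of any declared set of "
                f"{r.spec.name!r}")

    if r.style == "refined_triple" and len(comps) == 2:
        a, b = comps
        if a not in left_pool or b not in right_pool:
            return MembershipResult(False, "role-set",
                                    f"({a},{b}) uses a component on the "
                                    "wrong side")
        hit = any(split_label(e)[0] == a and split_label(e)[2] == b
                  for e in r.apex)
        if hit:
            return MembershipResult(True, None, "licensed instance")
        return MembershipResult(False, "constraint",
                                f"no constraint value links {a!r} and {b!r}")

    expected_len = 3 if r.style == "refined_triple" else 2
    if len(comps) != expected_len:
        return MembershipResult(False, "role-set",
                                f"expected {expected_len} components, "
                                f"got {len(comps)}")
    slots = (("left", comps[0]), ("right", comps[-1]))
    if r.style == "refined_triple":
        slots = (("left", comps[0]), ("constraint", comps[1]),
                 ("right", comps[2]))
    for side, value in slots:
        if value not in r.side_pools[side]:
            return MembershipResult(
                False, "role-set",
                f"{value!r} is not drawn from the {side} set")
    label = tuple_label(comps)
    if label in r.apex:
        return MembershipResult(True, None, "licensed instance")
    return MembershipResult(False, "constraint",
                            "components sit on the correct sides but "
                            "their attributes disagree")


@dataclass
class Architecture:
    """A realized relation plus a per-instance accessor assignment.

    Instances not listed use the canonical accessors; ``"swapped"``
    exchanges the outer accessors (the alternative construction that reads
    the left role through the right projection and vice versa).
    """

    relation: RealizedRelation
    accessors: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for inst, mode in self.accessors.items():
            if inst not in self.relation.apex:
                raise MalformedSpecError(
                    f"accessor assignment names {inst!r}, which is not an "
                    "instance of the relation")
            if mode not in ("canonical", "swapped"):
                raise MalformedSpecError(
                    f"unknown accessor mode {mode!r} for {inst!r}")


@dataclass(frozen=True)
class AuditFinding:
    instance: str
    role: str
    expected: str
    produced: str


@dataclass
class AuditReport:
    ok: bool
    instances_checked: int
    findings: list[AuditFinding]

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "instances_checked": self.instances_checked,
            "findings": [
                {"instance": f.instance, "role": f.role,
                 "expected": f.expected, "produced": f.produced}
                for f in self.findings
            ],
        }


def audit(arch: Architecture) -> AuditReport:
    """Check that every instance's accessors factor through one construction.

    Passes iff the per-instance inferred role values agree with the
    canonical projections everywhere; each disagreement is reported as
    (instance, role, expected, produced).
    """
    r = arch.relation
    if r.style == "quotient":
        raise WrongStyleError("audit applies to relation styles")
    by_side = r.spec.roles_by_side()
    left_role, right_role = by_side["left"], by_side["right"]
    findings: list[AuditFinding] = []
    for inst in r.apex:
        mode = arch.accessors.get(inst, "canonical")
        comps = split_label(inst)
        if mode == "swapped":
            produced = {left_role: comps[-1], right_role: comps[0]}
        else:
            produced = {left_role: comps[0], right_role: comps[-1]}
        for role in (left_role, right_role):
            expected = r.projections[role](inst)
            if produced[role] != expected:
                findings.append(
                    AuditFinding(inst, role, expected, produced[role]))
    return AuditReport(not findings, len(r.apex), findings)


# --------------------------------------------------------------------------
# block-matrix rendering
# --------------------------------------------------------------------------

@dataclass
class BlockMatrix:
    """Rows/columns grouped by shared attribute; filled cells = instances."""

    row_groups: list[tuple[str, list[str]]]   # (attribute, rows)
    col_groups: list[tuple[str, list[str]]]
    cells: set[tuple[str, str]]

    @property
    def filled(self) -> int:
        return len(self.cells)

    def to_dict(self) -> dict:
        return {
            "row_groups": [{"attribute": a, "rows": rows}
                           for a, rows in self.row_groups],
            "col_groups": [{"attribute": a, "cols": cols}
                           for a, cols in self.col_groups],
            "cells": sorted([list(c) for c in self.cells]),
        }

    def render_text(self) -> str:
        rows = [r for _, group in self.row_groups for r in group]
        cols = [c for _, group in self.col_groups for c in group]
        width = max([len(c) for c in cols + rows] + [1]) + 1
        lines = []
        header = " " * width + "".join(c.rjust(width) for c in cols)
        lines.append(header)
        for r in rows:
            cells = "".join(
                ("x" if (r, c) in self.cells else ".").rjust(width)
                for c in cols)
            lines.append(r.rjust(width) + cells)
        return "\n".join(lines)


def block_matrix(r: RealizedRelation) -> BlockMatrix:
    """The diagonal block-matrix view of a shared-constraint pullback."""
    if r.style != "shared_constraint":
        raise WrongStyleError(
            "block matrix rendering requires the shared_constraint style, "
            f"got {r.style!r}")
    lm = r.spec.map_for("left_map")
    rm = r.spec.map_for("right_map")
    attrs = sorted(set(lm.assignment.values())
                   | set(rm.assignment.values()))
    row_groups = [(a, sorted(x for x in lm.dom if lm(x) == a))
                  for a in attrs]
    col_groups = [(a, sorted(y for y in rm.dom if rm(y) == a))
                  for a in attrs]
    cells = {tuple(split_label(e)) for e in r.apex}
    return BlockMatrix([g for g in row_groups if g[1]],
                       [g for g in col_groups if g[1]],
                       cells)
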