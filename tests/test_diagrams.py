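"""Diagrams, commutativity, and the universal constructions with their
independent oracles (comprehension, grouping, union-find, exhaustive
search)."""

import pytest

from catsys import (Cone, Diagram, FinMap, FinSet, Shape, check_commutative,
                    coequalizer, colimit, compose, coproduct, enumerate_maps,
                    equalizer, identity, is_isomorphism, limit,
                    mediating_morphism, product, pullback, pushout, terminal,
                    split_label, tuple_label, verify_universal)
from catsys.diagrams import (discrete_shape, parallel_shape, product_set,
                             sink_shape)
from catsys.errors import (CodomainMismatchError, DomainMismatchError,
                           NoFactorizationError, NotParallelError, ShapeError)
from catsys.fixtures import fixture
from catsys.systematicity import realize


def parent_maps():
    spec = fixture("parent")
    return spec.map_for("left_map"), spec.map_for("right_map")


def parent_square(f, g, p1, p2, apex):
    shape = Shape(("A", "B", "C", "P"),
                  (("p1", "P", "A"), ("p2", "P", "B"),
                   ("f", "A", "C"), ("g", "B", "C")))
    return Diagram(shape,
                   {"P": apex, "A": f.dom, "B": g.dom, "C": f.cod},
                   {"p1": p1, "p2": p2, "f": f, "g": g})


class TestCommutativity:
    def test_single_edge_commutes_vacuously(self, abc, xy, map_factory):
        d = Diagram(Shape(("A", "B"), (("f", "A", "B"),)),
                    {"A": abc, "B": xy}, {"f": map_factory(abc, xy)})
        report = check_commutative(d)
        assert report.ok and report.pairs_checked == 0

    def test_parent_square_commutes(self):
        f, g = parent_maps()
        cone = pullback(f, g)
        d = parent_square(f, g, cone.legs["A"], cone.legs["B"], cone.apex)
        assert check_commutative(d).ok

    def test_corrupted_species_assignment_fails_with_witness(self):
        f, g = parent_maps()
        cone = pullback(f, g)
        bad = dict(f.assignment)
        bad["stallion"] = "bovine"  # corrupt one species assignment
        f_bad = FinMap(f.name, f.dom, f.cod, bad)
        d = parent_square(f_bad, g, cone.legs["A"], cone.legs["B"], cone.apex)
        report = check_commutative(d)
        assert not report.ok
        witnesses = {fail.witness for fail in report.failures}
        assert any("stallion" in w for w in witnesses)

    def test_cyclic_shape_requires_bound(self, abc):
        d = Diagram(Shape(("A",), (("loop", "A", "A"),)),
                    {"A": abc}, {"loop": identity(abc)})
        with pytest.raises(ShapeError):
            check_commutative(d, max_path_len=None)
        assert check_commutative(d, max_path_len=4).ok

    def test_acyclic_shape_needs_no_bound(self):
        f, g = parent_maps()
        cone = pullback(f, g)
        d = parent_square(f, g, cone.legs["A"], cone.legs["B"], cone.apex)
        assert check_commutative(d, max_path_len=None).ok


class TestProduct:
    def test_singletons(self):
        cone = product(FinSet("A", ("a",)), FinSet("B", ("b",)))
        assert cone.apex.elements == ("(a,b)",)

    def test_agents_product_contains_sue_loves_tom(self):
        agents = FinSet("Agents", ("John", "Mary", "Sue", "Tom"))
        cone = product(agents, agents)
        assert "(Sue,Tom)" in cone.apex
        assert len(cone.apex) == 16

    def test_cardinality_matches_nested_loop_oracle(self, abc, xy):
        cone = product(xy, abc)
        oracle = {tuple_label((x, y)) for x in xy for y in abc}
        assert set(cone.apex.elements) == oracle
        assert len(cone.apex) == 6


class TestPullback:
    def test_parent_fixture_prints_the_eight_pairs(self):
        f, g = parent_maps()
        cone = pullback(f, g)
        assert set(cone.apex.elements) == {
            "(stallion,colt)", "(stallion,filly)", "(mare,colt)",
            "(mare,filly)", "(bull,steer)", "(bull,heifer)",
            "(cow,steer)", "(cow,heifer)"}

    def test_singleton_constraint_gives_the_full_product(self, abc, xy):
        one = FinSet("1", ("*",))
        f = FinMap("f", abc, one, {x: "*" for x in abc})
        g = FinMap("g", xy, one, {x: "*" for x in xy})
        cone = pullback(f, g)
        assert cone.apex == product(abc, xy).apex

    def test_matches_comprehension_oracle_on_random_maps(self, map_factory):
        a = FinSet("A", (f"a{i}" for i in range(5)))
        b = FinSet("B", (f"b{i}" for i in range(5)))
        c = FinSet("C", ("c0", "c1", "c2"))
        for _ in range(40):
            f, g = map_factory(a, c), map_factory(b, c)
            oracle = {tuple_label((x, y))
                      for x in a for y in b if f(x) == g(y)}
            assert set(pullback(f, g).apex.elements) == oracle

    def test_codomain_mismatch_rejected(self, abc, xy, map_factory):
        f = map_factory(abc, xy)
        g = map_factory(xy, abc)
        with pytest.raises(CodomainMismatchError):
            pullback(f, g)


class TestEqualizer:
    def test_equal_maps_give_whole_domain(self, abc, xy, map_factory):
        f = map_factory(abc, xy)
        cone = equalizer(f, f)
        assert cone.apex == abc

    def test_identity_vs_constant(self, abc):
        const = FinMap("c", abc, abc, {x: "c" for x in abc})
        cone = equalizer(identity(abc), const)
        assert cone.apex.elements == ("c",)

    def test_equivalent_to_pullback_of_pairing_along_diagonal(
            self, map_factory):
        a = FinSet("A", ("a0", "a1", "a2", "a3"))
        b = FinSet("B", ("b0", "b1"))
        f, g = map_factory(a, b), map_factory(a, b)
        bb = product_set(b, b)
        pairing = FinMap("<f,g>", a, bb,
                         {x: tuple_label((f(x), g(x))) for x in a})
        diag = FinMap("diag", b, bb, {y: tuple_label((y, y)) for y in b})
        pb = pullback(pairing, diag)
        assert sorted(split_label(e)[0] for e in pb.apex) == \
            list(equalizer(f, g).apex.elements)

    def test_not_parallel_rejected(self, abc, xy, map_factory):
        with pytest.raises(NotParallelError):
            equalizer(map_factory(abc, xy), map_factory(xy, abc))


class TestColimits:
    def test_coproduct_is_tagged_disjoint_union(self, abc, xy):
        coc = coproduct(abc, xy)
        assert len(coc.apex) == len(abc) + len(xy)
        assert coc.legs["A"]("a") == "(l,a)"
        assert coc.legs["B"]("x") == "(r,x)"

    def test_coequalizer_of_equal_maps_is_discrete(self, abc, map_factory):
        f = map_factory(abc, abc)
        coc = coequalizer(f, f)
        assert all(len(members) == 1 for members in coc.classes.values())
        assert coc.apex == abc

    def test_absolute_kernel_pair_groups_sign_pairs(self):
        window = FinSet("W", (str(i) for i in range(-3, 4)))
        mags = FinSet("M", ("0", "1", "2", "3"))
        absm = FinMap("abs", window, mags,
                      {str(i): str(abs(i)) for i in range(-3, 4)})
        kp = pullback(absm, absm)
        coc = coequalizer(kp.legs["A"], kp.legs["B"])
        assert len(coc.classes) == 4
        grouped = {frozenset(m) for m in coc.classes.values()}
        assert frozenset({"3", "-3"}) in grouped

    def test_chain_of_identifications_collapses_to_one_class(self):
        dom = FinSet("D", ("1", "2"))
        cod = FinSet("E", ("x", "y", "z"))
        f = FinMap("f", dom, cod, {"1": "x", "2": "y"})
        g = FinMap("g", dom, cod, {"1": "y", "2": "z"})
        coc = coequalizer(f, g)
        assert len(coc.classes) == 1
        assert coc.apex.elements == ("x",)  # least member labels the class

    def test_pushout_via_codiagonal_recovers_coequalizer(self, map_factory):
        a = FinSet("A", ("a0", "a1", "a2"))
        b = FinSet("B", ("b0", "b1", "b2", "b3"))
        f, g = map_factory(a, b), map_factory(a, b)
        two_a = coproduct(a, a)
        codiag = FinMap("codiag", two_a.apex, a,
                        {e: split_label(e)[1] for e in two_a.apex})
        case = FinMap("[f,g]", two_a.apex, b,
                      {e: (f if split_label(e)[0] == "l" else g)(
                          split_label(e)[1]) for e in two_a.apex})
        po = pushout(codiag, case)
        q = po.legs["C"]  # the leg from b into the pushout apex
        po_partition = {}
        for x in b:
            po_partition.setdefault(q(x), set()).add(x)
        coeq_partition = {frozenset(m)
                          for m in coequalizer(f, g).classes.values()}
        assert {frozenset(m) for m in po_partition.values()} == coeq_partition

    def test_pushout_domain_mismatch_rejected(self, abc, xy, map_factory):
        with pytest.raises(DomainMismatchError):
            pushout(map_factory(abc, xy), map_factory(xy, abc))

    def test_coequalizer_classes_partition_codomain(self, map_factory):
        a = FinSet("A", (f"a{i}" for i in range(6)))
        b = FinSet("B", (f"b{i}" for i in range(5)))
        for _ in range(25):
            coc = coequalizer(map_factory(a, b), map_factory(a, b))
            members = sorted(m for c in coc.classes.values() for m in c)
            assert members == list(b.elements)

    def test_colimit_of_parallel_pair_matches_coequalizer(self, map_factory):
        a = FinSet("A", ("a0", "a1", "a2"))
        b = FinSet("B", ("b0", "b1", "b2"))
        f, g = map_factory(a, b), map_factory(a, b)
        d = Diagram(parallel_shape(), {"A": a, "B": b}, {"u": f, "v": g})
        coc = colimit(d)
        leg_b = coc.legs["B"]
        partition = {}
        for x in b:
            partition.setdefault(leg_b(x), set()).add(x)
        coeq = {frozenset(m) for m in coequalizer(f, g).classes.values()}
        assert {frozenset(m) for m in partition.values()} == coeq


class TestLimits:
    def test_empty_shape_gives_terminal_singleton(self):
        cone = terminal()
        assert len(cone.apex) == 1

    def test_discrete_two_node_limit_is_the_product(self, abc, xy):
        d = Diagram(discrete_shape(("A", "B")), {"A": abc, "B": xy}, {})
        cone = limit(d)
        assert cone.apex == product(abc, xy).apex

    def test_sink_limit_is_isomorphic_to_the_pullback(self):
        f, g = parent_maps()
        d = Diagram(sink_shape(), {"A": f.dom, "B": g.dom, "C": f.cod},
                    {"f": f, "g": g})
        lim = limit(d)
        pb = pullback(f, g)
        m = mediating_morphism(pb, lim)
        assert is_isomorphism(m).is_iso
        assert len(lim.apex) == len(pb.apex) == 8


class TestMediatingMorphism:
    def test_limit_to_itself_is_the_identity(self):
        f, g = parent_maps()
        pb = pullback(f, g)
        assert mediating_morphism(pb, pb) == identity(pb.apex)

    def test_one_element_cone_lands_on_mare_colt(self):
        f, g = parent_maps()
        pb = pullback(f, g)
        x = FinSet("X", ("*",))
        legs = {"A": FinMap("x1", x, f.dom, {"*": "mare"}),
                "B": FinMap("x2", x, g.dom, {"*": "colt"}),
                "C": FinMap("xc", x, f.cod, {"*": "equine"})}
        cone = Cone(x, legs, pb.diagram)
        assert mediating_morphism(cone, pb)("*") == "(mare,colt)"

    def test_agrees_with_exhaustive_search_survivor(self, map_factory):
        f, g = parent_maps()
        pb = pullback(f, g)
        x = FinSet("X", ("u", "v"))
        # random cone: pick apex elements, take their leg values
        for picks in [("(mare,colt)", "(bull,heifer)"),
                      ("(cow,steer)", "(cow,steer)")]:
            legs = {n: FinMap(f"leg{n}", x, pb.legs[n].cod,
                              {xx: pb.legs[n](p)
                               for xx, p in zip(x.elements, picks)})
                    for n in ("A", "B", "C")}
            cone = Cone(x, legs, pb.diagram)
            survivors = [m for m in enumerate_maps(x, pb.apex)
                         if all(compose(pb.legs[n], m) == cone.legs[n]
                                for n in ("A", "B", "C"))]
            assert len(survivors) == 1
            assert mediating_morphism(cone, pb) == survivors[0]

    def test_non_cone_cannot_factor(self):
        f, g = parent_maps()
        pb = pullback(f, g)
        x = FinSet("X", ("*",))
        legs = {"A": FinMap("x1", x, f.dom, {"*": "mare"}),
                "B": FinMap("x2", x, g.dom, {"*": "steer"}),  # wrong species
                "C": FinMap("xc", x, f.cod, {"*": "equine"})}
        with pytest.raises(NoFactorizationError):
            mediating_morphism(Cone(x, legs, pb.diagram), pb)


def _corrupt_duplicate(cone):
    """Add an apex element indistinguishable from an existing one."""
    dup_of = cone.apex.elements[0]
    apex = FinSet("dup", cone.apex.elements + ("zzz_dup",))
    legs = {n: FinMap(leg.name, apex, leg.cod,
                      {**leg.assignment, "zzz_dup": leg(dup_of)})
            for n, leg in cone.legs.items()}
    return Cone(apex, legs, cone.diagram)


def _corrupt_remove(cone):
    """Drop one apex element, keeping a genuine (non-universal) cone."""
    removed = cone.apex.elements[0]
    apex = FinSet("partial", cone.apex.elements[1:])
    legs = {n: FinMap(leg.name, apex, leg.cod,
                      {x: leg(x) for x in apex})
            for n, leg in cone.legs.items()}
    return Cone(apex, legs, cone.diagram)


class TestVerifyUniversal:
    def test_canonical_pullback_passes(self):
        f, g = parent_maps()
        report = verify_universal(pullback(f, g))
        assert report.ok and report.cones_tested > 0

    def test_swapped_projection_product_is_still_a_product(self, abc, xy):
        canonical = product(abc, xy)
        flipped = product(xy, abc)
        legs = {"A": FinMap("q1", flipped.apex, abc,
                            {e: split_label(e)[1] for e in flipped.apex}),
                "B": FinMap("q2", flipped.apex, xy,
                            {e: split_label(e)[0] for e in flipped.apex})}
        swapped = Cone(flipped.apex, legs, canonical.diagram)
        assert verify_universal(swapped).ok

    def test_duplicated_element_fails_uniqueness(self):
        f, g = parent_maps()
        report = verify_universal(_corrupt_duplicate(pullback(f, g)))
        assert not report.ok
        assert any(fail.factorizations >= 2 for fail in report.failures)

    def test_removed_element_fails_existence(self):
        f, g = parent_maps()
        report = verify_universal(_corrupt_remove(pullback(f, g)))
        assert not report.ok
        assert any(fail.factorizations == 0 for fail in report.failures)

    def test_two_universal_cones_related_by_unique_isomorphism(self, abc, xy):
        canonical = product(abc, xy)
        flipped = product(xy, abc)
        legs = {"A": FinMap("q1", flipped.apex, abc,
                            {e: split_label(e)[1] for e in flipped.apex}),
                "B": FinMap("q2", flipped.apex, xy,
                            {e: split_label(e)[0] for e in flipped.apex})}
        swapped = Cone(flipped.apex, legs, canonical.diagram)
        forward = mediating_morphism(swapped, canonical)
        backward = mediating_morphism(canonical, swapped)
        assert is_isomorphism(forward).is_iso
        assert compose(backward, forward) == identity(swapped.apex)
        assert compose(forward, backward) == identity(canonical.apex)
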