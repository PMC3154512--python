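"""Built-in domain fixtures and a seeded random-domain generator.

Every worked example ships as a ready-made :class:`DomainSpec`:

========================  =================  =========================================
name                      style              domain
========================  =================  =========================================
loves                     product            loves propositions over four agents
parent                    shared_constraint  progenitor/offspring constrained by species
parent_extended           refined_triple     whale/calf sense disambiguation
square                    characteristic     n -> n^2 on the window [-5, 5]
absolute                  quotient           |n| on the window [-3, 3]
less_than                 characteristic     a < b on the window {0..9}
subject_verb              shared_constraint  third-person subject-verb agreement
subject_verb_sheep        refined_triple     number-ambiguous nouns (*sheep*)
preposition               shared_constraint  verb-preposition selection (*onto* vs none)
========================  =================  =========================================

Integer-based domains use explicit finite windows chosen to contain every
worked instance; elements are decimal string labels.

The random generator emits shared-constraint domains with attribute maps
drawn uniformly over the constraint elements, using a self-contained
MINSTD linear congruential generator (x -> 48271 * x mod 2^31 - 1) so the
stream is reproducible across runtimes and languages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .core import FinMap, FinSet, tuple_label
from .errors import UnknownFixtureError
from .systematicity import DomainSpec


def _int_window(name: str, lo: int, hi: int) -> FinSet:
    return FinSet(name, (str(i) for i in range(lo, hi + 1)))


def _loves() -> DomainSpec:
    agents = FinSet("Agents", ("John", "Mary", "Sue", "Tom"))
    return DomainSpec(
        name="loves", style="product",
        sets={"Agents": agents}, maps={},
        roles={"lover": "left", "beloved": "right"},
        wiring={"left": "Agents", "right": "Agents"})


_PARENT_SPECIES = {
    "stallion": "equine", "mare": "equine",
    "bull": "bovine", "cow": "bovine",
}
_OFFSPRING_SPECIES = {
    "colt": "equine", "filly": "equine",
    "steer": "bovine", "heifer": "bovine",
}


def _parent() -> DomainSpec:
    pr = FinSet("Pr", _PARENT_SPECIES)
    off = FinSet("O", _OFFSPRING_SPECIES)
    species = FinSet("S", ("bovine", "equine"))
    f = FinMap("species_of_progenitor", pr, species, _PARENT_SPECIES)
    g = FinMap("species_of_offspring", off, species, _OFFSPRING_SPECIES)
    return DomainSpec(
        name="parent", style="shared_constraint",
        sets={"Pr": pr, "O": off, "S": species},
        maps={"species_of_progenitor": f, "species_of_offspring": g},
        roles={"progenitor": "left", "offspring": "right",
               "species": "constraint"},
        wiring={"left": "Pr", "right": "O", "constraint": "S",
                "left_map": "species_of_progenitor",
                "right_map": "species_of_offspring"})


def _parent_extended() -> DomainSpec:
    # parent-species pairs and species-offspring pairs; the two senses of
    # "calf" are separated by pairing it with bovine and with cetacean
    p1_pairs = [("stallion", "equine"), ("mare", "equine"),
                ("bull", "bovine"), ("cow", "bovine"),
                ("whale", "cetacean")]
    p2_pairs = [("equine", "colt"), ("equine", "filly"),
                ("bovine", "steer"), ("bovine", "heifer"),
                ("bovine", "calf"), ("cetacean", "calf")]
    species = FinSet("S", ("bovine", "cetacean", "equine"))
    p1 = FinSet("P1", (tuple_label(p) for p in p1_pairs))
    p2 = FinSet("P2", (tuple_label(p) for p in p2_pairs))
    f = FinMap("species_of_pair", p1, species,
               {tuple_label(p): p[1] for p in p1_pairs})
    g = FinMap("pair_species", p2, species,
               {tuple_label(p): p[0] for p in p2_pairs})
    return DomainSpec(
        name="parent_extended", style="refined_triple",
        sets={"P1": p1, "P2": p2, "S": species},
        maps={"species_of_pair": f, "pair_species": g},
        roles={"progenitor": "left", "offspring": "right",
               "species": "constraint"},
        wiring={"left_pairs": "P1", "right_pairs": "P2", "constraint": "S",
                "left_map": "species_of_pair",
                "right_map": "pair_species"})


def _square() -> DomainSpec:
    roots = _int_window("Roots", -5, 5)
    squares = _int_window("Squares", 0, 25)
    relation = tuple(sorted((str(n), str(n * n)) for n in range(-5, 6)))
    return DomainSpec(
        name="square", style="characteristic",
        sets={"Roots": roots, "Squares": squares}, maps={},
        roles={"root": "left", "square": "right"},
        wiring={"left": "Roots", "right": "Squares"},
        relation=relation)


def _absolute() -> DomainSpec:
    window = _int_window("Window", -3, 3)
    magnitudes = _int_window("Magnitudes", 0, 3)
    classifier = FinMap("abs", window, magnitudes,
                        {str(n): str(abs(n)) for n in range(-3, 4)})
    return DomainSpec(
        name="absolute", style="quotient",
        sets={"Window": window, "Magnitudes": magnitudes},
        maps={"abs": classifier},
        roles={},
        wiring={"base": "Window", "classifier": "abs"})


def _less_than() -> DomainSpec:
    numbers = _int_window("Numbers", 0, 9)
    relation = tuple(sorted((str(a), str(b))
                            for a in range(10) for b in range(10) if a < b))
    return DomainSpec(
        name="less_than", style="characteristic",
        sets={"Numbers": numbers}, maps={},
        roles={"lesser": "left", "greater": "right"},
        wiring={"left": "Numbers", "right": "Numbers"},
        relation=relation)


_NOUN_NUMBER = {"dog": "singular", "dogs": "plural",
                "cat": "singular", "cats": "plural"}
_VERB_NUMBER = {"chases": "singular", "chase": "plural"}


def _subject_verb() -> DomainSpec:
    nouns = FinSet("N", _NOUN_NUMBER)
    verbs = FinSet("V", _VERB_NUMBER)
    attrs = FinSet("A", ("plural", "singular"))
    f = FinMap("noun_number", nouns, attrs, _NOUN_NUMBER)
    g = FinMap("verb_number", verbs, attrs, _VERB_NUMBER)
    return DomainSpec(
        name="subject_verb", style="shared_constraint",
        sets={"N": nouns, "V": verbs, "A": attrs},
        maps={"noun_number": f, "verb_number": g},
        roles={"subject": "left", "verb": "right", "number": "constraint"},
        wiring={"left": "N", "right": "V", "constraint": "A",
                "left_map": "noun_number", "right_map": "verb_number"})


def _subject_verb_sheep() -> DomainSpec:
    # sheep carries both numbers, so noun-number PAIRS are the left object
    np_pairs = [("farmer", "singular"),
                ("sheep", "singular"), ("sheep", "plural")]
    vp_pairs = [("singular", "chases"), ("plural", "chase")]
    attrs = FinSet("A", ("plural", "singular"))
    np = FinSet("NP", (tuple_label(p) for p in np_pairs))
    vp = FinSet("VP", (tuple_label(p) for p in vp_pairs))
    f = FinMap("noun_pair_number", np, attrs,
               {tuple_label(p): p[1] for p in np_pairs})
    g = FinMap("verb_pair_number", vp, attrs,
               {tuple_label(p): p[0] for p in vp_pairs})
    return DomainSpec(
        name="subject_verb_sheep", style="refined_triple",
        sets={"NP": np, "VP": vp, "A": attrs},
        maps={"noun_pair_number": f, "verb_pair_number": g},
        roles={"subject": "left", "verb": "right", "number": "constraint"},
        wiring={"left_pairs": "NP", "right_pairs": "VP", "constraint": "A",
                "left_map": "noun_pair_number",
                "right_map": "verb_pair_number"})


_VERB_PREP = {"dripped": "required", "threw": "required",
              "poured": "required", "tossed": "required",
              "dampened": "not-required", "drenched": "not-required",
              "wet": "not-required"}
_PREP_ATTR = {"onto": "required", "over": "required",
              "no-preposition": "not-required"}


def _preposition() -> DomainSpec:
    verbs = FinSet("V", _VERB_PREP)
    preps = FinSet("P", _PREP_ATTR)
    attrs = FinSet("A", ("not-required", "required"))
    f = FinMap("verb_requirement", verbs, attrs, _VERB_PREP)
    g = FinMap("prep_requirement", preps, attrs, _PREP_ATTR)
    return DomainSpec(
        name="preposition", style="shared_constraint",
        sets={"V": verbs, "P": preps, "A": attrs},
        maps={"verb_requirement": f, "prep_requirement": g},
        roles={"verb": "left", "preposition": "right",
               "requirement": "constraint"},
        wiring={"left": "V", "right": "P", "constraint": "A",
                "left_map": "verb_requirement",
                "right_map": "prep_requirement"})


_CATALOG: dict[str, Callable[[], DomainSpec]] = {
    "loves": _loves,
    "parent": _parent,
    "parent_extended": _parent_extended,
    "square": _square,
    "absolute": _absolute,
    "less_than": _less_than,
    "subject_verb": _subject_verb,
    "subject_verb_sheep": _subject_verb_sheep,
    "preposition": _preposition,
}


def fixture_names() -> list[str]:
    return sorted(_CATALOG)


def fixture(name: str) -> DomainSpec:
    """A fresh copy of the named catalog fixture."""
    try:
        builder = _CATALOG[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: "
            f"{', '.join(fixture_names())}") from None
    return builder()


# --------------------------------------------------------------------------
# seeded random domains
# --------------------------------------------------------------------------

_MINSTD_MOD = 2**31 - 1
_MINSTD_MULT = 48271


class Minstd:
    """MINSTD linear congruential generator; portable and tiny.

    State evolves as ``x -> 48271 * x mod (2^31 - 1)``; a zero seed is
    shifted to 1 (the recurrence has no zero state).
    """

    def __init__(self, seed: int):
        self.state = (seed % _MINSTD_MOD) or 1

    def next(self) -> int:
        self.state = (self.state * _MINSTD_MULT) % _MINSTD_MOD
        return self.state

    def below(self, n: int) -> int:
        """Uniform-ish draw in [0, n); modulo bias is negligible here."""
        return self.next() % n


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a generated shared-constraint domain."""

    seed: int
    n_left: int = 5
    n_right: int = 5
    n_constraint: int = 3
    forced_empty_block: bool = False

    def __post_init__(self):
        if min(self.n_left, self.n_right, self.n_constraint) < 0:
            raise ValueError("set sizes must be non-negative")


def random_domain(cfg: SynthConfig) -> DomainSpec:
    """A seeded shared-constraint domain with uniform attribute maps.

    With ``forced_empty_block`` the left map avoids the first constraint
    value, guaranteeing at least one empty diagonal block.
    """
    rng = Minstd(cfg.seed)
    k = max(cfg.n_constraint, 1)
    constraint = FinSet("K", (f"k{i:02d}" for i in range(k)))
    left = FinSet("L", (f"l{i:02d}" for i in range(cfg.n_left)))
    right = FinSet("R", (f"r{i:02d}" for i in range(cfg.n_right)))
    if cfg.forced_empty_block and k > 1:
        left_assign = {x: f"k{1 + rng.below(k - 1):02d}" for x in left}
    else:
        left_assign = {x: f"k{rng.below(k):02d}" for x in left}
    right_assign = {y: f"k{rng.below(k):02d}" for y in right}
    f = FinMap("left_attr", left, constraint, left_assign)
    g = FinMap("right_attr", right, constraint, right_assign)
    return DomainSpec(
        name=f"random-{cfg.seed}", style="shared_constraint",
        sets={"L": left, "R": right, "K": constraint},
        maps={"left_attr": f, "right_attr": g},
        roles={"first": "left", "second": "right", "attr": "constraint"},
        wiring={"left": "L", "right": "R", "constraint": "K",
                "left_map": "left_attr", "right_map": "right_attr"})
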