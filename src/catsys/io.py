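"""Reading and writing domain specs in the JSON dialect.

A spec document is a JSON object::

    {
      "format_version": 1,
      "name": "parent",
      "style": "shared_constraint",
      "sets":  {"Pr": ["bull", "cow", ...], ...},
      "maps":  {"species_of_progenitor":
                   {"dom": "Pr", "cod": "S", "assign": {"bull": "bovine", ...}}},
      "roles": {"progenitor": "left", ...},
      "wiring": {"left": "Pr", "right": "O", "constraint": "S",
                 "left_map": "species_of_progenitor",
                 "right_map": "species_of_offspring"},
      "relation": [["2", "3"], ...],          # characteristic style only
      "windows": {"Roots": [-5, 5]}           # optional integer shorthand
    }

``windows`` entries materialize into explicit decimal label sets at read
time, so the core never sees integers.  A ``.yaml``/``.yml`` path reads
the identical schema through the YAML surface.  Writing always emits the
explicit JSON form, sorted, so write/read round-trips are identities and
output is byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

import yaml

from .core import FinMap, FinSet
from .errors import IntegrityError, SchemaError
from .systematicity import STYLES, DomainSpec

FORMAT_VERSION = 1

_TOP_KEYS = {"format_version", "name", "style", "sets", "maps",
             "roles", "wiring", "relation", "windows"}


def spec_to_document(spec: DomainSpec) -> dict:
    doc: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "name": spec.name,
        "style": spec.style,
        "sets": {n: list(s.elements) for n, s in sorted(spec.sets.items())},
        "maps": {n: {"dom": m.dom.name, "cod": m.cod.name,
                     "assign": dict(sorted(m.assignment.items()))}
                 for n, m in sorted(spec.maps.items())},
        "roles": dict(sorted(spec.roles.items())),
        "wiring": dict(sorted(spec.wiring.items())),
    }
    if spec.relation is not None:
        doc["relation"] = [list(pair) for pair in spec.relation]
    return doc


def _expect(condition: bool, location: str, message: str) -> None:
    if not condition:
        raise SchemaError(location, message)


def document_to_spec(doc: Any) -> DomainSpec:
    _expect(isinstance(doc, dict), "/", "document must be a JSON object")
    unknown = set(doc) - _TOP_KEYS
    _expect(not unknown, "/", f"unknown keys: {sorted(unknown)}")
    for key in ("name", "style", "sets"):
        _expect(key in doc, f"/{key}", "required key missing")
    _expect(doc.get("format_version", FORMAT_VERSION) == FORMAT_VERSION,
            "/format_version", f"expected {FORMAT_VERSION}")
    _expect(isinstance(doc["name"], str), "/name", "must be a string")
    _expect(doc["style"] in STYLES, "/style",
            f"must be one of {', '.join(STYLES)}")

    _expect(isinstance(doc["sets"], dict), "/sets", "must be an object")
    sets: dict[str, FinSet] = {}
    for name, elems in doc["sets"].items():
        loc = f"/sets/{name}"
        _expect(isinstance(elems, list)
                and all(isinstance(e, str) for e in elems),
                loc, "must be a list of strings")
        try:
            sets[name] = FinSet(name, elems)
        except ValueError as exc:
            raise SchemaError(loc, str(exc)) from None

    for name, window in (doc.get("windows") or {}).items():
        loc = f"/windows/{name}"
        _expect(isinstance(window, list) and len(window) == 2
                and all(isinstance(v, int) for v in window),
                loc, "must be a [lo, hi] integer pair")
        lo, hi = window
        _expect(lo <= hi, loc, "window must be non-empty")
        _expect(name not in sets, loc, "window shadows an explicit set")
        sets[name] = FinSet(name, (str(i) for i in range(lo, hi + 1)))

    maps: dict[str, FinMap] = {}
    for name, body in (doc.get("maps") or {}).items():
        loc = f"/maps/{name}"
        _expect(isinstance(body, dict), loc, "must be an object")
        for key in ("dom", "cod", "assign"):
            _expect(key in body, f"{loc}/{key}", "required key missing")
        for end in ("dom", "cod"):
            if body[end] not in sets:
                raise IntegrityError(
                    f"map {name!r} references undeclared set {body[end]!r}")
        _expect(isinstance(body["assign"], dict), f"{loc}/assign",
                "must be an object")
        try:
            maps[name] = FinMap(name, sets[body["dom"]], sets[body["cod"]],
                                body["assign"])
        except ValueError as exc:
            raise IntegrityError(f"map {name!r}: {exc}") from None

    roles = doc.get("roles") or {}
    _expect(isinstance(roles, dict)
            and all(isinstance(v, str) for v in roles.values()),
            "/roles", "must map role names to sides")

    wiring = doc.get("wiring") or {}
    _expect(isinstance(wiring, dict)
            and all(isinstance(v, str) for v in wiring.values()),
            "/wiring", "must map slots to set/map names")
    for slot, name in wiring.items():
        if name not in sets and name not in maps:
            raise IntegrityError(
                f"wiring slot {slot!r} references undeclared name {name!r}")

    relation = None
    if doc.get("relation") is not None:
        _expect(isinstance(doc["relation"], list), "/relation",
                "must be a list of pairs")
        pairs = []
        for i, pair in enumerate(doc["relation"]):
            _expect(isinstance(pair, list) and len(pair) == 2
                    and all(isinstance(v, str) for v in pair),
                    f"/relation/{i}", "must be a [a, b] string pair")
            pairs.append(tuple(pair))
        relation = tuple(sorted(pairs))
    elif doc["style"] == "characteristic":
        raise SchemaError("/relation",
                          "characteristic style requires a relation list")

    spec = DomainSpec(name=doc["name"], style=doc["style"], sets=sets,
                      maps=maps, roles=dict(roles), wiring=dict(wiring),
                      relation=relation)
    spec.validate()
    return spec


def dumps_spec(spec: DomainSpec) -> str:
    return json.dumps(spec_to_document(spec), indent=2, sort_keys=True) + "\n"


def write_spec(spec: DomainSpec, path: Union[str, Path]) -> None:
    Path(path).write_text(dumps_spec(spec))


def read_spec(path: Union[str, Path]) -> DomainSpec:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError("/", f"not valid JSON: {exc}") from None
    return document_to_spec(doc)
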