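# catsys

A finite category theory engine for **(quasi-)systematicity** in cognitive
architecture.  It constructs — and, more importantly, *verifies* — the
universal constructions (products, pullbacks, equalizers, coequalizers,
pushouts, generic limits and colimits, and the diagonal ⊣ product
adjunction) that explain why cognitive capacities come in intrinsically
connected groups, and it realizes a collection of concrete cognitive
domains (relational inference, formal relations like *square* and
*less-than*, subject–verb agreement, verb–preposition selection) as
executable, auditable architectures.

## Who it is for

Researchers in computational cognitive science who want the
category-theoretic account of systematicity to be *checkable*: every
claim of the form "this object with these accessor maps is a pullback" or
"these two functors are adjoint" is discharged by exhaustive verification
over finite sets, not taken on faith.

## The core idea

Systematicity is the fact that having some cognitive capacities implies
having certain structurally related others — anyone who can infer *John*
as the lover from *John loves Mary* can infer *Mary* as the lover from
*Mary loves John*.  Modelling construction as a functor and access as
projections, a fully systematic relation over A and B is a **product**
A × B with projections π₁, π₂: every pair of maps (f₁, f₂): X → (A, B)
factors through the product by exactly one mediating morphism
⟨f₁, f₂⟩, and the product participates in the adjunction Δ ⊣ × (diagonal
functor left adjoint to product functor) with unit η: a ↦ (a, a) and
counit ε = (π₁, π₂).

Most real domains are only *quasi*-systematic: not every combination of
constituents is licensed.  The engine models such a relation as a
**pullback** — a product constrained at a shared attribute object C:

```
P ──π₂──▶ B
│          │g          P = A ×_C B = {(a, b) | f(a) = g(b)}
π₁         ▼
▼          C
A ───f────▶
```

*mares parent colts* but not *mares parent steers*: the progenitor and
offspring maps into the species object agree exactly on the licensed
pairs.  Relations that are not functions (e.g. *less-than*) use the
subobject-classifier pattern: the pullback of the relation's
characteristic map χ: A×B → Ω along true: 1 → Ω.  Equivalences (e.g.
n and −n are the "same" under *absolute*) are kernel-pair coequalizers.

What singles out the systematic architecture is **uniqueness of the
mediating morphism**: an architecture that mixes accessor conventions
(canonical projections for some instances, swapped ones for others)
cannot factor through one construction, and the engine's audit reports
exactly the instances that betray it.

## Worked example

```bash
$ catsys build --fixture parent
relation parent [shared_constraint]
apex (8 instances):
  (bull,heifer)
  (bull,steer)
  (cow,heifer)
  (cow,steer)
  (mare,colt)
  (mare,filly)
  (stallion,colt)
  (stallion,filly)
projection progenitor:
  (bull,heifer) -> bull
  ...
```

The apex is exactly the eight licensed *parent* propositions — the
pullback of the two species maps keeps (mare, colt) and excludes
(mare, steer).  Verification discharges the universal property by
exhaustive probing:

```bash
$ catsys verify --fixture parent
relation parent [shared_constraint]
  commutativity: PASS (1 path pairs)
  universal property: PASS (73 cones tested)
  overall: PASS
```

(73 cones: every cone over the species sink whose apex has 0, 1 or 2
elements; each factored through the pullback in exactly one way.)

An architecture that reads some instances through swapped accessors
fails the audit with the precise counterexample:

```bash
$ catsys audit --fixture loves --swap "(Mary,John)"
audit loves: FAIL (16 instances)
  instance (Mary,John): role lover produced John, expected Mary
  instance (Mary,John): role beloved produced Mary, expected John
$ echo $?
1
```

In the library the same objects are first-class:

```python
from catsys import realize, infer, membership
from catsys.fixtures import fixture

square = realize(fixture("square"))
infer(square, "square", {"root": "4"})        # '16'

sv = realize(fixture("subject_verb"))
membership(sv, "(dogs,chases)")
# MembershipResult(member=False, reason='constraint', ...)
```

Other commands: `catsys render --fixture parent` draws the block-matrix
view (two diagonal blocks, equine and bovine, 8 filled cells);
`catsys demo` runs every catalog fixture end-to-end and exits nonzero on
any failure.

## Domain specs

Domains are plain JSON (or YAML) documents declaring finite sets, maps,
a construction style (`product`, `shared_constraint`, `refined_triple`,
`characteristic`, `quotient`), role names and the wiring between them;
see `catsys.io` for the schema and `catsys.fixtures` for nine ready-made
examples.  Integer windows such as `"windows": {"Roots": [-5, 5]}`
materialize into label sets at read time.

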