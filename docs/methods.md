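# Methods

## The ambient category

All constructions live in the category of finite sets and total
functions.  Objects (`FinSet`) hold distinct opaque string labels in
canonical lexicographic order; morphisms (`FinMap`) are explicit
assignment tables.  Equality is extensional everywhere — two sets are
equal when they hold the same labels, two maps when their endpoints and
tables agree — because every argument the engine checks compares maps
extensionally; names are display handles only.

Ordered pairs and triples are encoded as parenthesized comma-joined
labels, `"(mare,colt)"`, `"(whale,cetacean,calf)"`, with a
balanced-parenthesis splitter for decoding.  Nesting therefore costs
nothing: the apex of one construction is a plain object to the next.

Empty-set conventions are the standard ones: exactly one map out of the
empty set, none into it from a nonempty set, and `|B|^|A|` total maps in
general (so `0^0 = 1`).

Infinite domains are out of scope by design.  Integer-based relations
(square, less-than, absolute value) are handled through explicit finite
windows declared by the domain spec — roots [−5, 5] with squares
[0, 25], less-than on {0..9}, absolute value on [−3, 3] — chosen to
contain every worked instance.  This finite-window policy is the
package's own restriction, not a claim about the modelled domains.

## Commutativity checking

A diagram commutes when any two paths with the same endpoints (at least
one of length > 1) compose to the same map.  The checker enumerates all
edge-paths up to a bound (default 8, ample for every diagram the package
constructs), composes each, and reports every failing path pair with a
witnessing element.  Cyclic shapes require a finite bound; acyclic shapes
may pass `None`, which falls back to the edge count (the longest simple
path).

## Universal constructions

Canonical constructions are computed set-theoretically:

* product — all pairs, with coordinate projections;
* pullback — pairs agreeing under the two maps into the shared codomain;
* equalizer — the agreeing subset with its inclusion;
* coproduct — the tagged disjoint union `(l,x)` / `(r,y)`;
* coequalizer / pushout / colimit — quotients by the generated
  equivalence, computed with a deterministic union–find;
* limit — all node-indexed matching families, encoded as tuples in
  sorted node order (the empty shape yields the terminal singleton).

Quotient classes are labelled by their lexicographically least member
rather than a set literal, so class labels remain ordinary elements and
quotients compose with everything else.  A consequence worth knowing:
the class of {3, −3} under *absolute* is labelled `-3`, since `"-3"`
sorts before `"3"`.

### Verifying universality

`verify_universal` quantifies over probe apexes of sizes 0, 1 and 2 on a
fixed two-letter alphabet (plus any caller-supplied apexes), enumerates
*every* cone over the diagram with that apex, and counts the mediating
maps into the candidate; universality demands exactly one per cone.  Full
quantification over all finite sets is impossible, but size ≤ 2 probes
already separate the failure modes: a missing apex element fails
existence at a singleton probe, a redundant one fails uniqueness.  The
mediating-map count is computed in factored form — the number of apex
elements matching each probe element's leg signature, multiplied over
probe elements — which equals what a literal enumeration of
`Hom(X, apex)` would count, in polynomial rather than exponential time.
The test suite separately checks `mediating_morphism` against the
literal filter-the-enumeration search.

Enumerations are guarded by a cap (default 10⁶ candidates) that fails
loudly with the required count rather than stalling.

## The adjunction check

`verify_adjunction` takes the candidate left and right functors with a
unit and a counit and checks, over all probes:

1. typing and naturality of both transformations,
2. both triangle identities,
3. the universal factorization: for every pair map f = (f₁, f₂) out of
   Δ(A) there must be exactly one h: A → ×(B) with ε₁∘h = f₁ and
   ε₂∘h = f₂, **and** that unique h must equal ×(f)∘η_A — the map the
   adjunction itself constructs.

The last consistency clause is the operative one.  A product with
exchanged projections is still a product (it passes
`verify_universal`), and exchanging the projections of *every* instance
is merely an isomorphic relabelling; what fails is pairing the standard
unit with exchanged counit components.  On heterogeneous pairs the
exchanged counit is not even well-typed; on homogeneous pairs it breaks
the right triangle identity and the factorization consistency.  That is
exactly the mixed-architecture failure the audit exposes at the instance
level.

Functors are represented extensionally (callables on demand), not as
total tables: the ambient category is far too large to tabulate, and the
laws are checked on probes.

The pullback adjunction is verified through the universal property of
the sink-shaped limit rather than by building a functor category: the
simplified outer-objects presentation determines the inner morphism, and
the engine always reconstructs and checks it rather than omitting it.

## Domain styles

`realize` turns a `DomainSpec` into an apex + projections + witness
diagram:

* **product** — fully systematic relations (the *loves* propositions over
  agents {John, Mary, Sue, Tom});
* **shared_constraint** — pullback of two attribute maps into a common
  constraint object (*parent* over species, subject–verb agreement over
  grammatical number, verb–preposition selection over the
  preposition-requirement attribute);
* **refined_triple** — pullback of two *pair*-sets sharing their
  constraint coordinate, apex elements flattened to triples with the
  constraint in the middle.  This separates sense ambiguity: *calf*
  pairs with both bovine and cetacean, so (whale, cetacean, calf) is
  licensed while nothing links whale and steer.  The number-ambiguous
  noun *sheep* works the same way, carrying both singular and plural
  attributes;
* **characteristic** — an arbitrary explicit relation rebuilt as the
  pullback of its characteristic map χ: A×B → Ω along true: 1 → Ω, with
  Ω = {false, true} and the truth inclusion fixed at "true" (the truth
  object's internals are conventional; the universal property pins the
  construction regardless);
* **quotient** — the kernel-pair coequalizer of a classifier map, whose
  classes are the classifier's fibers and whose quotient is isomorphic
  to the classifier's image.

Membership failures are classified exhaustively: a component on the
wrong side is a *role-set* violation, components on the correct sides
whose attributes disagree are a *constraint* violation, and a component
in no declared set is an error, not a rejection.

The audit criterion is mediating-factorization agreement restated
element-wise: an architecture (instance → canonical/swapped accessor
assignment) passes iff every instance's accessor readings coincide with
the canonical projections.  Only asymmetric instances can betray a swap,
so the counterexample set is exactly the swapped non-symmetric
instances.

Inference selectors are equality constraints on role values only, which
keeps `infer` total and decidable; the selector must identify exactly
one instance.

## Synthetic domains

`random_domain` generates shared-constraint specs with attribute maps
drawn uniformly and independently over the constraint elements, so the
expected apex size is n·m/k — the property suite checks the 500-seed
mean against that expectation within three standard errors.  Randomness
comes from a self-contained MINSTD linear congruential generator
(x → 48271·x mod 2³¹−1, zero seed shifted to 1) so the stream is
reproducible across runtimes and even languages; draws below a bound use
a plain modulus (the bias is irrelevant at these sizes).  The generator
emulates the *combinatorial* structure of quasi-systematic domains —
two role sets partitioned by a shared attribute — and nothing else: no
lexical frequency, no graded membership, no attribute correlation.
Passing property suites therefore speak to the correctness of the
constructions, not to the realism of any particular linguistic corpus.

## Problem sizes and determinism

Everything is desk-scale by construction: the largest catalog objects
are the 11×26 characteristic product of the square window (≈ 330 000
candidate leg families at the largest probe) and the 45-element
less-than apex, and the full verification of all nine fixtures completes
in seconds.  All orderings are lexicographic, serialization sorts keys,
and the CLI emits no timestamps or paths, so repeated runs are
byte-identical at a fixed seed.

## Known limitations

* Only the category of finite sets; no enriched, weighted or
  higher-categorical constructions.
* Probe-based verification is a documented approximation to "for every
  object", sound for the failure modes in scope but not a proof for all
  of Set.
* Agreement fixtures cover third-person only; first/second person and
  the semantics of preposition selection are out of scope.
* Partial maps and multi-valued relations are not morphisms; relations
  enter only through characteristic maps.
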