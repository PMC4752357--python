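"""EL-fragment classification: normalization + completion-rule saturation.

Muscle definitions in the ontology are EL class expressions (conjunctions
of existential restrictions over attachments, innervation and
development), so the full subsumption hierarchy is computable in
polynomial time by the classic EL completion-rule calculus:

* axioms are rewritten into four normal forms —
  NF1 ``A ⊑ B``, NF2 ``A1 ⊓ A2 ⊑ B``, NF3 ``A ⊑ ∃r.B``, NF4 ``∃r.A ⊑ B`` —
  introducing deterministically named fresh classes for complex
  subexpressions;
* per-class subsumer sets ``S(·)`` and per-property role-pair sets ``R(·)``
  are saturated to the least fixpoint of rules R1–R6 (including role
  transitivity and the property hierarchy).

The fixpoint is independent of rule-application order; a worklist keyed by
newly derived facts is used purely for performance. The worst case is
polynomial (O(n^2) subsumer entries and O(n^2) role pairs per property,
each touched a bounded number of times per normal axiom), so saturation
terminates on all valid inputs. Every derived fact records the rule and
premises that first produced it, so any reported subsumption can be
explained by a replayable derivation trace.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .errors import DanglingReferenceError, NoEntailmentError
from .model import (
    Axiom,
    ClassExpression,
    Conjunction,
    Curie,
    EquivalentTo,
    Existential,
    Named,
    ObjectProperty,
    Ontology,
    SubClassOf,
    named_classes_in,
    properties_in,
)

__all__ = [
    "NF1",
    "NF2",
    "NF3",
    "NF4",
    "NormalAxiom",
    "TOP",
    "FRESH_PREFIX",
    "normalize",
    "normalize_axioms",
    "saturate",
    "classify",
    "Saturation",
    "DerivationTrace",
    "explain",
    "entails",
]

#: implicit top class; every class is subsumed by it (no bottom — the
#: fragment has no negation or disjointness)
TOP = Curie("owl", "Thing")

#: prefix of deterministically generated fresh class names (``_:NF<n>``);
#: fresh names never appear in user-facing results
FRESH_PREFIX = "_"


@dataclass(frozen=True)
class NF1:
    """A ⊑ B (both named)."""

    sub: Curie
    sup: Curie


@dataclass(frozen=True)
class NF2:
    """A1 ⊓ A2 ⊑ B."""

    a1: Curie
    a2: Curie
    sup: Curie


@dataclass(frozen=True)
class NF3:
    """A ⊑ ∃r.B."""

    sub: Curie
    prop: Curie
    filler: Curie


@dataclass(frozen=True)
class NF4:
    """∃r.A ⊑ B."""

    prop: Curie
    filler: Curie
    sup: Curie


NormalAxiom = Union[NF1, NF2, NF3, NF4]

# Facts are tuples: ("S", a, b) for b ∈ S(a); ("R", r, a, b) for (a,b) ∈ R(r).
Fact = tuple


def _check_properties(axioms: Iterable[Axiom], properties: dict[Curie, ObjectProperty]):
    for axiom in axioms:
        exprs = (
            (axiom.sub, axiom.sup)
            if isinstance(axiom, SubClassOf)
            else (axiom.definition,)
        )
        for expr in exprs:
            for prop in properties_in(expr):
                if prop not in properties:
                    raise DanglingReferenceError(
                        f"expression references undeclared property {prop}"
                    )


def normalize_axioms(
    axioms: Sequence[Axiom], properties: dict[Curie, ObjectProperty]
) -> list[NormalAxiom]:
    """Rewrite arbitrary EL axioms into normal forms NF1–NF4.

    Each ``EquivalentTo(A, D)`` is split into ``A ⊑ D`` and ``D ⊑ A``
    before rewriting. Complex fillers and complex left sides are replaced
    by fresh names ``_:NF1, _:NF2, ...`` in a fixed traversal order, and
    conjunctions are binarized left-to-right over the canonical conjunct
    order, so the output is deterministic for a given axiom list.
    """
    _check_properties(axioms, properties)
    counter = 0

    def fresh() -> Curie:
        nonlocal counter
        counter += 1
        return Curie(FRESH_PREFIX, f"NF{counter}")

    queue: deque[tuple[ClassExpression, ClassExpression]] = deque()
    for axiom in axioms:
        if isinstance(axiom, EquivalentTo):
            queue.append((Named(axiom.cls), axiom.definition))
            queue.append((axiom.definition, Named(axiom.cls)))
        else:
            queue.append((axiom.sub, axiom.sup))

    out: list[NormalAxiom] = []
    while queue:
        sub, sup = queue.popleft()
        if isinstance(sup, Conjunction):
            # C ⊑ D1 ⊓ ... ⊓ Dn  ≡  C ⊑ Di for each i
            for conjunct in sup.conjuncts:
                queue.append((sub, conjunct))
        elif isinstance(sub, Named):
            if isinstance(sup, Named):
                out.append(NF1(sub.cls, sup.cls))
            else:  # sup is Existential
                if isinstance(sup.filler, Named):
                    out.append(NF3(sub.cls, sup.prop, sup.filler.cls))
                else:
                    n = fresh()
                    out.append(NF3(sub.cls, sup.prop, n))
                    queue.append((Named(n), sup.filler))
        elif isinstance(sub, Existential):
            if isinstance(sup, Named):
                if isinstance(sub.filler, Named):
                    out.append(NF4(sub.prop, sub.filler.cls, sup.cls))
                else:
                    n = fresh()
                    queue.append((sub.filler, Named(n)))
                    out.append(NF4(sub.prop, n, sup.cls))
            else:  # GCI with complex right side: split through a fresh name
                n = fresh()
                queue.append((sub, Named(n)))
                queue.append((Named(n), sup))
        else:  # sub is Conjunction
            if isinstance(sup, Named):
                operands: list[Curie] = []
                for conjunct in sub.conjuncts:
                    if isinstance(conjunct, Named):
                        operands.append(conjunct.cls)
                    else:
                        n = fresh()
                        queue.append((conjunct, Named(n)))
                        operands.append(n)
                left = operands[0]
                for middle in operands[1:-1]:
                    g = fresh()
                    out.append(NF2(left, middle, g))
                    left = g
                out.append(NF2(left, operands[-1], sup.cls))
            else:
                n = fresh()
                queue.append((sub, Named(n)))
                queue.append((Named(n), sup))
    return out


def normalize(ontology: Ontology) -> list[NormalAxiom]:
    """Normalize all axioms of an ontology (see :func:`normalize_axioms`)."""
    return normalize_axioms(ontology.axioms, ontology.properties)


@dataclass
class Saturation:
    """The saturated consequences of a normalized axiom set.

    ``subsumers[A]`` is the set S(A) of (named, possibly fresh) subsumers
    of A, always containing A itself and ⊤; ``role_pairs[r]`` is the set
    R(r) of entailed pairs (A, B) with ``A ⊑ ∃r.B``. Fresh normalization
    names are listed in ``fresh_names`` and are filtered from all reported
    results. ``equivalence_groups`` partitions the original classes by
    mutual subsumption.
    """

    subsumers: dict[Curie, set[Curie]]
    role_pairs: dict[Curie, set[tuple[Curie, Curie]]]
    equivalence_groups: tuple[frozenset[Curie], ...]
    fresh_names: frozenset[Curie]
    originals: frozenset[Curie]
    axioms: tuple[NormalAxiom, ...]
    traces: dict[Fact, tuple[str, tuple]] = field(default_factory=dict, repr=False)

    # -- reported views (original named classes only) -------------------

    def subsumers_of(self, cls: Curie, reflexive: bool = True) -> frozenset[Curie]:
        out = {
            c
            for c in self.subsumers.get(cls, set())
            if c in self.originals and (reflexive or c != cls)
        }
        return frozenset(out)

    def descendants_of(self, cls: Curie, strict: bool = True) -> frozenset[Curie]:
        out = {
            a
            for a in self.originals
            if cls in self.subsumers.get(a, set()) and not (strict and a == cls)
        }
        return frozenset(out)

    def is_entailed(self, sub: Curie, sup: Curie) -> bool:
        return sup in self.subsumers.get(sub, set())

    def role_closure(self, prop: Curie) -> frozenset[tuple[Curie, Curie]]:
        return frozenset(
            (a, b)
            for a, b in self.role_pairs.get(prop, set())
            if a in self.originals and b in self.originals
        )

    def group_of(self, cls: Curie) -> frozenset[Curie]:
        for group in self.equivalence_groups:
            if cls in group:
                return group
        return frozenset({cls})


def _property_ancestors(
    properties: dict[Curie, ObjectProperty]
) -> dict[Curie, frozenset[Curie]]:
    ancestors: dict[Curie, frozenset[Curie]] = {}

    def visit(p: Curie) -> frozenset[Curie]:
        if p in ancestors:
            return ancestors[p]
        out: set[Curie] = set()
        for parent in properties[p].parent_properties:
            out.add(parent)
            out |= visit(parent)
        ancestors[p] = frozenset(out)
        return ancestors[p]

    for p in properties:
        visit(p)
    return ancestors


def saturate(
    normal_axioms: Sequence[NormalAxiom],
    properties: dict[Curie, ObjectProperty],
    extra_classes: Iterable[Curie] = (),
) -> Saturation:
    """Compute the least fixpoint of the EL completion rules.

    R1: A' ∈ S(A), A' ⊑ B                      ⇒ B ∈ S(A)
    R2: A1, A2 ∈ S(A), A1 ⊓ A2 ⊑ B             ⇒ B ∈ S(A)
    R3: A' ∈ S(A), A' ⊑ ∃r.B                   ⇒ (A, B) ∈ R(r)
    R4: (A, B) ∈ R(r), B' ∈ S(B), ∃r.B' ⊑ C    ⇒ C ∈ S(A)
    R5: (A, B), (B, C) ∈ R(r), r transitive    ⇒ (A, C) ∈ R(r)
    R6: (A, B) ∈ R(r), r ⊑ s                   ⇒ (A, B) ∈ R(s)
    """
    universe: set[Curie] = set(extra_classes)
    for ax in normal_axioms:
        if isinstance(ax, NF1):
            universe.update((ax.sub, ax.sup))
        elif isinstance(ax, NF2):
            universe.update((ax.a1, ax.a2, ax.sup))
        elif isinstance(ax, NF3):
            universe.update((ax.sub, ax.filler))
        else:
            universe.update((ax.filler, ax.sup))

    nf1_by_sub: dict[Curie, list[NF1]] = {}
    nf2_by_operand: dict[Curie, list[NF2]] = {}
    nf3_by_sub: dict[Curie, list[NF3]] = {}
    nf4_by_prop_filler: dict[tuple[Curie, Curie], list[NF4]] = {}
    for ax in normal_axioms:
        if isinstance(ax, NF1):
            nf1_by_sub.setdefault(ax.sub, []).append(ax)
        elif isinstance(ax, NF2):
            nf2_by_operand.setdefault(ax.a1, []).append(ax)
            if ax.a2 != ax.a1:
                nf2_by_operand.setdefault(ax.a2, []).append(ax)
        elif isinstance(ax, NF3):
            nf3_by_sub.setdefault(ax.sub, []).append(ax)
        else:
            nf4_by_prop_filler.setdefault((ax.prop, ax.filler), []).append(ax)

    ancestors = _property_ancestors(properties)

    S: dict[Curie, set[Curie]] = {c: set() for c in universe}
    S[TOP] = {TOP}
    R: dict[Curie, set[tuple[Curie, Curie]]] = {}
    out_idx: dict[Curie, dict[Curie, set[Curie]]] = {}  # r -> a -> {b}
    in_idx: dict[Curie, dict[Curie, set[Curie]]] = {}  # r -> b -> {a}
    in_pairs_all: dict[Curie, set[tuple[Curie, Curie]]] = {}  # b -> {(r, a)}
    traces: dict[Fact, tuple[str, tuple]] = {}
    work: deque[Fact] = deque()

    def add_sub(a: Curie, b: Curie, rule: str, premises: tuple) -> None:
        bucket = S.setdefault(a, set())
        if b not in bucket:
            bucket.add(b)
            fact = ("S", a, b)
            traces[fact] = (rule, premises)
            work.append(fact)

    def add_role(r: Curie, a: Curie, b: Curie, rule: str, premises: tuple) -> None:
        bucket = R.setdefault(r, set())
        if (a, b) not in bucket:
            bucket.add((a, b))
            out_idx.setdefault(r, {}).setdefault(a, set()).add(b)
            in_idx.setdefault(r, {}).setdefault(b, set()).add(a)
            in_pairs_all.setdefault(b, set()).add((r, a))
            fact = ("R", r, a, b)
            traces[fact] = (rule, premises)
            work.append(fact)

    for cls in sorted(universe, key=str):
        add_sub(cls, cls, "init", ())
        add_sub(cls, TOP, "top", ())

    while work:
        fact = work.popleft()
        if fact[0] == "S":
            _, a, b_new = fact
            for ax in nf1_by_sub.get(b_new, ()):
                add_sub(a, ax.sup, "R1", (fact, ax))
            for ax in nf2_by_operand.get(b_new, ()):
                if ax.a1 in S[a] and ax.a2 in S[a]:
                    add_sub(a, ax.sup, "R2", (("S", a, ax.a1), ("S", a, ax.a2), ax))
            for ax in nf3_by_sub.get(b_new, ()):
                add_role(ax.prop, a, ax.filler, "R3", (fact, ax))
            # a appears as the target of existing role pairs: rule R4
            for r, x in list(in_pairs_all.get(a, ())):
                for ax in nf4_by_prop_filler.get((r, b_new), ()):
                    add_sub(x, ax.sup, "R4", (("R", r, x, a), fact, ax))
        else:
            _, r, a, b = fact
            for b_sup in list(S.get(b, ())):
                for ax in nf4_by_prop_filler.get((r, b_sup), ()):
                    add_sub(a, ax.sup, "R4", (fact, ("S", b, b_sup), ax))
            prop = properties.get(r)
            if prop is not None and prop.is_transitive:
                for c in list(out_idx.get(r, {}).get(b, ())):
                    add_role(r, a, c, "R5", (fact, ("R", r, b, c)))
                for x in list(in_idx.get(r, {}).get(a, ())):
                    add_role(r, x, b, "R5", (("R", r, x, a), fact))
            for s in ancestors.get(r, ()):
                add_role(s, a, b, "R6", (fact,))

    fresh = frozenset(c for c in S if c.prefix == FRESH_PREFIX)
    originals = frozenset(c for c in universe if c.prefix != FRESH_PREFIX and c != TOP)

    groups: list[frozenset[Curie]] = []
    seen: set[Curie] = set()
    for cls in sorted(originals, key=str):
        if cls in seen:
            continue
        group = frozenset(
            other
            for other in originals
            if other in S[cls] and cls in S.get(other, set())
        )
        seen |= group
        groups.append(group)

    return Saturation(
        subsumers=S,
        role_pairs=R,
        equivalence_groups=tuple(groups),
        fresh_names=fresh,
        originals=originals,
        axioms=tuple(normal_axioms),
        traces=traces,
    )


def classify(ontology: Ontology) -> Saturation:
    """Normalize and saturate a whole ontology.

    Equivalence groups are computed from mutual subsumption over the
    original named classes; cyclic subsumptions are reported as groups,
    not errors (standard DL semantics).
    """
    axioms = normalize(ontology)
    return saturate(axioms, ontology.properties, extra_classes=ontology.classes.keys())


# --------------------------------------------------------------------------
# Entailment of complex expressions


def entails(
    ontology: Ontology, sub: ClassExpression, sup: ClassExpression
) -> bool:
    """Decide whether the ontology entails ``sub ⊑ sup``.

    Uses the standard reduction: probe names ``Q_sub ⊑ sub`` and
    ``sup ⊑ Q_sup`` are added and the extended axiom set is re-saturated;
    the entailment holds iff ``Q_sup ∈ S(Q_sub)``.
    """
    q_sub = Curie(FRESH_PREFIX, "probe_sub")
    q_sup = Curie(FRESH_PREFIX, "probe_sup")
    extended: list[Axiom] = list(ontology.axioms)
    extended.append(SubClassOf(Named(q_sub), sub))
    extended.append(SubClassOf(sup, Named(q_sup)))
    axioms = normalize_axioms(extended, ontology.properties)
    sat = saturate(
        axioms, ontology.properties, extra_classes=set(ontology.classes) | {q_sub, q_sup}
    )
    return q_sup in sat.subsumers[q_sub]


# --------------------------------------------------------------------------
# Explanation


@dataclass
class DerivationTrace:
    """One well-founded derivation of an inferred fact.

    ``conclusion`` is a fact tuple (``("S", A, B)`` or ``("R", r, A, B)``),
    ``rule`` is the completion-rule tag that produced it ("init", "top",
    "R1"–"R6"), and ``premises`` are the traces of the facts it consumed
    plus the normal axioms used as side conditions.
    """

    conclusion: Fact
    rule: str
    premises: tuple[Union["DerivationTrace", NormalAxiom], ...]

    def steps(self) -> int:
        return 1 + sum(
            p.steps() for p in self.premises if isinstance(p, DerivationTrace)
        )

    def rules_used(self) -> frozenset[str]:
        out = {self.rule}
        for p in self.premises:
            if isinstance(p, DerivationTrace):
                out |= p.rules_used()
        return frozenset(out)


def _trace_for(saturation: Saturation, fact: Fact, memo: dict) -> DerivationTrace:
    if fact in memo:
        return memo[fact]
    rule, premises = saturation.traces[fact]
    resolved = tuple(
        p if not isinstance(p, tuple) else _trace_for(saturation, p, memo)
        for p in premises
    )
    trace = DerivationTrace(conclusion=fact, rule=rule, premises=resolved)
    memo[fact] = trace
    return trace


def explain(saturation: Saturation, sub: Curie, sup: Curie) -> DerivationTrace:
    """Return one replayable derivation of ``sub ⊑ sup``.

    Premise facts are resolved recursively to their own traces; traces are
    well-founded because each fact records the (already derived) premises
    that first produced it.
    """
    fact = ("S", sub, sup)
    if fact not in saturation.traces:
        raise NoEntailmentError(f"{sub} ⊑ {sup} is not entailed")
    return _trace_for(saturation, fact, {})


def explain_role(saturation: Saturation, prop: Curie, sub: Curie, filler: Curie) -> DerivationTrace:
    """Return one replayable derivation of ``sub ⊑ ∃prop.filler``."""
    fact = ("R", prop, sub, filler)
    if fact not in saturation.traces:
        raise NoEntailmentError(f"{sub} ⊑ ∃{prop}.{filler} is not entailed")
    return _trace_for(saturation, fact, {})
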