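"""In-memory representation of an anatomy ontology.

The model follows the conventions of the OBO family of anatomy ontologies
(Uberon and its relatives): classes carry a CURIE identifier, a label,
synonyms and cross-references; object properties (relations such as
``part_of`` or ``innervated_by``) may be transitive and arranged in a
hierarchy; and the logical content is a list of axioms over class
expressions drawn from the EL fragment of OWL — named classes, existential
restrictions (``property some filler``) and conjunctions.

Equivalence axioms hold the necessary-and-sufficient muscle definitions
(attachments + innervation); general class inclusions (GCIs), whose left
side is itself complex, encode rules such as "innervated by the trigeminal
nerve implies develops from branchial arch 1".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

from .errors import (
    AmbiguousTermError,
    DanglingReferenceError,
    OntologyValidationError,
    UnknownTermError,
)

__all__ = [
    "Curie",
    "OntologyClass",
    "ObjectProperty",
    "Named",
    "Existential",
    "Conjunction",
    "ClassExpression",
    "conjunction_of",
    "expression_key",
    "named_classes_in",
    "properties_in",
    "SubClassOf",
    "EquivalentTo",
    "Axiom",
    "Ontology",
    "resolve_label",
    "normalize_text",
]

_CURIE_COLON = re.compile(r"^([A-Za-z_][A-Za-z0-9_.-]*):(\S+)$")
_CURIE_UNDERSCORE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)_(\d+)$")


@dataclass(frozen=True, order=True)
class Curie:
    """A compact identifier ``PREFIX:NNNNNNN`` (e.g. ``MFMO:0000066``).

    The OBO purl form ``MFMO_0000066`` is accepted on parse and rendered
    back in colon form; comparison is plain string equality.
    """

    prefix: str
    local_id: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    @classmethod
    def parse(cls, text: str) -> "Curie":
        text = text.strip()
        m = _CURIE_COLON.match(text)
        if m:
            return cls(m.group(1), m.group(2))
        m = _CURIE_UNDERSCORE.match(text)
        if m:
            return cls(m.group(1), m.group(2))
        raise ValueError(f"not a CURIE: {text!r}")

    @staticmethod
    def looks_like(text: str) -> bool:
        text = text.strip()
        return bool(_CURIE_COLON.match(text) or _CURIE_UNDERSCORE.match(text))


_WS = re.compile(r"\s+")
_QUOTES = str.maketrans({"‘": "'", "’": "'", "“": '"', "”": '"'})


def normalize_text(text: str) -> str:
    """Case-fold a label for lookup: lowercase, collapse internal whitespace,
    normalize typographic quotes to straight ones."""
    return _WS.sub(" ", text.translate(_QUOTES).strip()).casefold()


@dataclass
class OntologyClass:
    """A named class (term): a muscle, bone, nerve or other structure."""

    id: Curie
    label: str
    synonyms: tuple[str, ...] = ()
    xrefs: tuple[Curie, ...] = ()
    text_def: str | None = None
    def_source: str | None = None
    annotations: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise OntologyValidationError(f"class {self.id} has an empty label")
        folded = [normalize_text(s) for s in self.synonyms]
        if len(set(folded)) != len(folded):
            raise OntologyValidationError(f"class {self.id} has duplicate synonyms")
        if normalize_text(self.label) in folded:
            raise OntologyValidationError(
                f"class {self.id}: synonym equals the label {self.label!r}"
            )


@dataclass
class ObjectProperty:
    """An object property (relation), e.g. ``part_of`` or ``attached_to``.

    Transitivity is per-property and not inherited along the property
    hierarchy.
    """

    id: Curie
    label: str
    is_transitive: bool = False
    parent_properties: tuple[Curie, ...] = ()


# --------------------------------------------------------------------------
# Class expressions


@dataclass(frozen=True)
class Named:
    cls: Curie


@dataclass(frozen=True)
class Existential:
    prop: Curie
    filler: "ClassExpression"


@dataclass(frozen=True)
class Conjunction:
    conjuncts: tuple["ClassExpression", ...]

    def __post_init__(self) -> None:
        if len(self.conjuncts) < 2:
            raise ValueError("a Conjunction needs at least two conjuncts")
        if any(isinstance(c, Conjunction) for c in self.conjuncts):
            raise ValueError("Conjunction must be flattened (no nested Conjunction)")
        if list(self.conjuncts) != sorted(self.conjuncts, key=expression_key):
            raise ValueError("conjuncts must be in canonical (sorted) order")


ClassExpression = Union[Named, Existential, Conjunction]


def expression_key(expr: ClassExpression):
    """Total order on expressions; defines the canonical conjunct order."""
    if isinstance(expr, Named):
        return (0, str(expr.cls))
    if isinstance(expr, Existential):
        return (1, str(expr.prop), expression_key(expr.filler))
    return (2, tuple(expression_key(c) for c in expr.conjuncts))


def conjunction_of(items: Iterable[ClassExpression]) -> ClassExpression:
    """Build a canonical conjunction: flattened, deduplicated, sorted.

    A single distinct conjunct collapses to that expression itself.
    """
    flat: list[ClassExpression] = []
    for item in items:
        if isinstance(item, Conjunction):
            flat.extend(item.conjuncts)
        else:
            flat.append(item)
    unique = sorted(set(flat), key=expression_key)
    if not unique:
        raise ValueError("empty conjunction")
    if len(unique) == 1:
        return unique[0]
    return Conjunction(tuple(unique))


def named_classes_in(expr: ClassExpression) -> Iterator[Curie]:
    if isinstance(expr, Named):
        yield expr.cls
    elif isinstance(expr, Existential):
        yield from named_classes_in(expr.filler)
    else:
        for c in expr.conjuncts:
            yield from named_classes_in(c)


def properties_in(expr: ClassExpression) -> Iterator[Curie]:
    if isinstance(expr, Existential):
        yield expr.prop
        yield from properties_in(expr.filler)
    elif isinstance(expr, Conjunction):
        for c in expr.conjuncts:
            yield from properties_in(c)


# --------------------------------------------------------------------------
# Axioms


@dataclass(frozen=True)
class SubClassOf:
    """``sub SubClassOf sup``. A complex ``sub`` makes this a GCI."""

    sub: ClassExpression
    sup: ClassExpression


@dataclass(frozen=True)
class EquivalentTo:
    """Necessary-and-sufficient definition of a named class."""

    cls: Curie
    definition: ClassExpression


Axiom = Union[SubClassOf, EquivalentTo]


def _axiom_expressions(axiom: Axiom) -> Iterator[ClassExpression]:
    if isinstance(axiom, SubClassOf):
        yield axiom.sub
        yield axiom.sup
    else:
        yield Named(axiom.cls)
        yield axiom.definition


# --------------------------------------------------------------------------
# Ontology container


@dataclass
class Ontology:
    """An ontology: classes, object properties and axioms.

    ``validate`` enforces the container invariants: every CURIE referenced
    by an axiom is declared, labels are unique after case-folding, and the
    property hierarchy is acyclic.
    """

    classes: dict[Curie, OntologyClass] = field(default_factory=dict)
    properties: dict[Curie, ObjectProperty] = field(default_factory=dict)
    axioms: list[Axiom] = field(default_factory=list)

    # -- construction helpers -------------------------------------------

    def add_class(self, cls: OntologyClass) -> OntologyClass:
        if cls.id in self.classes:
            raise OntologyValidationError(f"duplicate class id {cls.id}")
        self.classes[cls.id] = cls
        return cls

    def add_property(self, prop: ObjectProperty) -> ObjectProperty:
        if prop.id in self.properties:
            raise OntologyValidationError(f"duplicate property id {prop.id}")
        self.properties[prop.id] = prop
        return prop

    # -- lookups --------------------------------------------------------

    def label_of(self, curie: Curie) -> str:
        if curie in self.classes:
            return self.classes[curie].label
        if curie in self.properties:
            return self.properties[curie].label
        return str(curie)

    def _label_tables(self) -> tuple[dict[str, Curie], dict[str, list[Curie]]]:
        labels: dict[str, Curie] = {}
        synonyms: dict[str, list[Curie]] = {}
        for cls in self.classes.values():
            labels[normalize_text(cls.label)] = cls.id
            for syn in cls.synonyms:
                synonyms.setdefault(normalize_text(syn), []).append(cls.id)
        return labels, synonyms

    def resolve_label(self, text: str) -> Curie:
        """Resolve a CURIE string, label or synonym to a class id.

        Matching is case-insensitive with whitespace and typographic-quote
        normalization; CURIEs win over labels, labels over synonyms.
        """
        stripped = text.strip().strip("'‘’")
        if Curie.looks_like(stripped):
            try:
                curie = Curie.parse(stripped)
            except ValueError:
                curie = None
            if curie is not None and curie in self.classes:
                return curie
        labels, synonyms = self._label_tables()
        folded = normalize_text(text).strip("'")
        if folded in labels:
            return labels[folded]
        if folded in synonyms:
            candidates = synonyms[folded]
            if len(set(candidates)) > 1:
                raise AmbiguousTermError(text, candidates)
            return candidates[0]
        raise UnknownTermError(f"unknown term: {text!r}")

    def resolve_property(self, text: str) -> Curie:
        """Resolve a property CURIE string or label; ``attached to`` and
        ``attached_to`` are equivalent."""
        stripped = text.strip().strip("'‘’")
        if Curie.looks_like(stripped):
            try:
                curie = Curie.parse(stripped)
            except ValueError:
                curie = None
            if curie is not None and curie in self.properties:
                return curie
        folded = normalize_text(text).strip("'").replace("_", " ")
        for prop in self.properties.values():
            if normalize_text(prop.label).replace("_", " ") == folded:
                return prop.id
        raise UnknownTermError(f"unknown property: {text!r}")

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        seen_labels: dict[str, Curie] = {}
        for cls in self.classes.values():
            folded = normalize_text(cls.label)
            if folded in seen_labels and seen_labels[folded] != cls.id:
                raise OntologyValidationError(
                    f"duplicate label {cls.label!r} on {seen_labels[folded]} and {cls.id}"
                )
            seen_labels[folded] = cls.id
            for xref in cls.xrefs:
                if not isinstance(xref, Curie):
                    raise OntologyValidationError(f"class {cls.id}: bad xref {xref!r}")
        for prop in self.properties.values():
            for parent in prop.parent_properties:
                if parent not in self.properties:
                    raise DanglingReferenceError(
                        f"property {prop.id} references undeclared parent {parent}"
                    )
        self._check_property_acyclicity()
        for axiom in self.axioms:
            for expr in _axiom_expressions(axiom):
                for curie in named_classes_in(expr):
                    if curie not in self.classes:
                        raise DanglingReferenceError(
                            f"axiom references undeclared class {curie}"
                        )
                for curie in properties_in(expr):
                    if curie not in self.properties:
                        raise DanglingReferenceError(
                            f"axiom references undeclared property {curie}"
                        )

    def _check_property_acyclicity(self) -> None:
        state: dict[Curie, int] = {}  # 0 visiting, 1 done

        def visit(p: Curie, stack: tuple[Curie, ...]) -> None:
            if state.get(p) == 1:
                return
            if state.get(p) == 0:
                raise OntologyValidationError(
                    f"property hierarchy cycle through {p}: {' -> '.join(map(str, stack))}"
                )
            state[p] = 0
            for parent in self.properties[p].parent_properties:
                visit(parent, stack + (parent,))
            state[p] = 1

        for p in self.properties:
            visit(p, (p,))

    # -- structural comparison ------------------------------------------

    def structurally_equal(self, other: "Ontology") -> bool:
        """Order-insensitive structural equality (axioms as a multiset)."""
        if self.classes.keys() != other.classes.keys():
            return False
        for cid, cls in self.classes.items():
            o = other.classes[cid]
            if (
                cls.label != o.label
                or sorted(cls.synonyms) != sorted(o.synonyms)
                or sorted(cls.xrefs) != sorted(o.xrefs)
                or cls.text_def != o.text_def
                or cls.def_source != o.def_source
                or sorted(cls.annotations) != sorted(o.annotations)
            ):
                return False
        if self.properties.keys() != other.properties.keys():
            return False
        for pid, prop in self.properties.items():
            o = other.properties[pid]
            if (
                prop.label != o.label
                or prop.is_transitive != o.is_transitive
                or sorted(prop.parent_properties) != sorted(o.parent_properties)
            ):
                return False
        from collections import Counter

        return Counter(self.axioms) == Counter(other.axioms)


def resolve_label(ontology: Ontology, text: str) -> Curie:
    """Functional form of :meth:`Ontology.resolve_label`."""
    return ontology.resolve_label(text)
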