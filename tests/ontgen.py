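"""Seeded random-ontology generator for property tests.

Ontologies are small (bounded classes/axioms/properties) and exercise the
full axiom vocabulary: plain subclass links, existential restrictions,
conjunction definitions and GCIs, synonyms/xrefs/annotations for the
round-trip tests, and a transitive property with a parent property for
the role rules.
"""

from __future__ import annotations

import random

from muscle_logic.model import (
    Conjunction,
    Curie,
    EquivalentTo,
    Existential,
    Named,
    ObjectProperty,
    Ontology,
    OntologyClass,
    SubClassOf,
    conjunction_of,
)


def random_ontology(
    seed: int,
    max_classes: int = 30,
    max_axioms: int = 60,
    max_properties: int = 3,
    with_decorations: bool = False,
) -> Ontology:
    rng = random.Random(seed)
    onto = Ontology()

    n_props = rng.randint(1, max_properties)
    props: list[Curie] = []
    for i in range(n_props):
        pid = Curie("RP", f"{i:07d}")
        parents = ()
        # occasional property hierarchy (always acyclic: parent has lower index)
        if i > 0 and rng.random() < 0.3:
            parents = (props[rng.randrange(i)],)
        onto.add_property(
            ObjectProperty(
                pid,
                f"rel {i}",
                is_transitive=rng.random() < 0.5,
                parent_properties=parents,
            )
        )
        props.append(pid)

    n_classes = rng.randint(2, max_classes)
    classes: list[Curie] = []
    for i in range(n_classes):
        cid = Curie("RC", f"{i:07d}")
        synonyms = ()
        xrefs = ()
        annotations = ()
        if with_decorations:
            if rng.random() < 0.3:
                synonyms = tuple(
                    f"alias {i} {j}" for j in range(rng.randint(1, 2))
                )
            if rng.random() < 0.2:
                xrefs = (Curie("XR", f"{rng.randrange(1000):07d}"),)
            if rng.random() < 0.2:
                annotations = (("comment", f"generated note {i}"),)
        text_def = (
            f"generated class {i}" if with_decorations and rng.random() < 0.3 else None
        )
        onto.add_class(
            OntologyClass(
                cid,
                f"class {i:03d}",
                synonyms=synonyms,
                xrefs=xrefs,
                text_def=text_def,
                def_source="generator" if text_def and rng.random() < 0.5 else None,
                annotations=annotations,
            )
        )
        classes.append(cid)

    def named() -> Named:
        return Named(rng.choice(classes))

    def existential(depth: int) -> Existential:
        return Existential(rng.choice(props), expr(depth - 1))

    def expr(depth: int):
        roll = rng.random()
        if depth <= 0 or roll < 0.5:
            return named()
        if roll < 0.8:
            return existential(depth)
        return conjunction_of([expr(depth - 1) for _ in range(rng.randint(2, 3))])

    n_axioms = rng.randint(1, max_axioms)
    defined: set[Curie] = set()
    for _ in range(n_axioms):
        roll = rng.random()
        if roll < 0.45:  # plain subclass link
            onto.axioms.append(SubClassOf(named(), named()))
        elif roll < 0.7:  # existential on either side
            if rng.random() < 0.5:
                onto.axioms.append(SubClassOf(named(), existential(1)))
            else:
                onto.axioms.append(SubClassOf(existential(1), named()))
        elif roll < 0.85:  # GCI or complex-right subclass
            onto.axioms.append(SubClassOf(expr(2), expr(2)))
        else:  # equivalence definition (at most one per class)
            cls = rng.choice(classes)
            if cls in defined:
                onto.axioms.append(SubClassOf(named(), named()))
            else:
                defined.add(cls)
                body = expr(2)
                if isinstance(body, Named) and body.cls == cls:
                    body = conjunction_of([body, existential(1)])
                onto.axioms.append(EquivalentTo(cls, body))

    onto.validate()
    return onto
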