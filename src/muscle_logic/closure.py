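"""Pre-reasoning: materialize the full subclass closure and closures along
selected transitive properties, for consumption by databases that have no
reasoner of their own.

The exporter classifies the ontology, then flattens every entailed
``A ⊑ B`` pair and, for each selected transitive property ``r``, every
entailed ``A ⊑ ∃r.B`` pair (restricted to the original named classes)
into a reasoner-free artifact. Each pair carries a provenance flag so
consumers can distinguish what was asserted from what was inferred. All
entailed existential pairs are materialized, which is a superset of
asserted-plus-transitive-chains (documented behavior).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError
from .model import (
    Curie,
    Existential,
    Named,
    ObjectProperty,
    Ontology,
    OntologyClass,
    SubClassOf,
)
from .reasoner import Saturation, classify

__all__ = ["PreReasonedOntology", "export_closure", "write_closure"]


@dataclass
class PreReasonedOntology:
    """Materialized closures; pair -> True if asserted, False if inferred.

    ``subclass_closure`` is reflexive-transitively closed; each property
    closure is transitively closed for its (transitive) property;
    asserted pairs are a subset of the closure.
    """

    subclass_closure: dict[tuple[Curie, Curie], bool]
    property_closures: dict[Curie, dict[tuple[Curie, Curie], bool]]
    ontology: Ontology
    include_reflexive: bool = True

    def pair_count(self) -> int:
        return len(self.subclass_closure) + sum(
            len(pairs) for pairs in self.property_closures.values()
        )


def export_closure(
    ontology: Ontology,
    selected_properties: list[Curie],
    include_reflexive: bool = True,
    saturation: Saturation | None = None,
) -> PreReasonedOntology:
    """Compute the pre-reasoned closure of an ontology.

    ``selected_properties`` must be declared and flagged transitive — the
    closure semantics of a non-transitive property differ, so selecting
    one is an explicit configuration error. Reflexive subclass pairs
    (A, A) are included by default and always flagged as inferred.
    """
    for prop in selected_properties:
        if prop not in ontology.properties:
            raise ConfigurationError(f"property {prop} is not declared")
        if not ontology.properties[prop].is_transitive:
            raise ConfigurationError(
                f"property {prop} ({ontology.properties[prop].label}) is not "
                "transitive; closure along it is not supported"
            )
    sat = saturation if saturation is not None else classify(ontology)

    asserted_subclass = {
        (ax.sub.cls, ax.sup.cls)
        for ax in ontology.axioms
        if isinstance(ax, SubClassOf)
        and isinstance(ax.sub, Named)
        and isinstance(ax.sup, Named)
    }
    asserted_rel: dict[Curie, set[tuple[Curie, Curie]]] = {}
    for ax in ontology.axioms:
        if (
            isinstance(ax, SubClassOf)
            and isinstance(ax.sub, Named)
            and isinstance(ax.sup, Existential)
            and isinstance(ax.sup.filler, Named)
        ):
            asserted_rel.setdefault(ax.sup.prop, set()).add(
                (ax.sub.cls, ax.sup.filler.cls)
            )

    subclass: dict[tuple[Curie, Curie], bool] = {}
    for a in sorted(sat.originals, key=str):
        for b in sorted(sat.subsumers_of(a), key=str):
            if a == b and not include_reflexive:
                continue
            subclass[(a, b)] = (a, b) in asserted_subclass and a != b

    prop_closures: dict[Curie, dict[tuple[Curie, Curie], bool]] = {}
    for prop in selected_properties:
        pairs: dict[tuple[Curie, Curie], bool] = {}
        for a, b in sorted(sat.role_closure(prop), key=lambda p: (str(p[0]), str(p[1]))):
            pairs[(a, b)] = (a, b) in asserted_rel.get(prop, set())
        prop_closures[prop] = pairs

    return PreReasonedOntology(
        subclass_closure=subclass,
        property_closures=prop_closures,
        ontology=ontology,
        include_reflexive=include_reflexive,
    )


def _rel_label(ontology: Ontology, prop: Curie) -> str:
    return ontology.properties[prop].label if prop in ontology.properties else str(prop)


def dumps_closure_tsv(pre: PreReasonedOntology) -> str:
    """TSV rows ``sub  rel  sup  provenance``, sorted; header included."""
    rows = []
    for (a, b), asserted in pre.subclass_closure.items():
        rows.append((str(a), "is_a", str(b), "asserted" if asserted else "inferred"))
    for prop, pairs in pre.property_closures.items():
        rel = _rel_label(pre.ontology, prop)
        for (a, b), asserted in pairs.items():
            rows.append((str(a), rel, str(b), "asserted" if asserted else "inferred"))
    lines = ["sub\trel\tsup\tprovenance"]
    lines.extend("\t".join(row) for row in sorted(rows))
    return "\n".join(lines) + "\n"


def dumps_closure_obo(pre: PreReasonedOntology) -> str:
    """OBO with every closure pair materialized as a direct is_a /
    relationship tag (reflexive pairs omitted — a term is trivially its
    own subclass). Re-reading and re-exporting this output is a fixpoint:
    the closure of a materialized ontology is itself."""
    from .obo import dumps_obo

    src = pre.ontology
    flat = Ontology()
    for cls in src.classes.values():
        flat.add_class(
            OntologyClass(
                id=cls.id,
                label=cls.label,
                synonyms=cls.synonyms,
                xrefs=cls.xrefs,
                text_def=cls.text_def,
                def_source=cls.def_source,
                annotations=cls.annotations,
            )
        )
    for prop in src.properties.values():
        flat.add_property(
            ObjectProperty(
                id=prop.id,
                label=prop.label,
                is_transitive=prop.is_transitive,
                parent_properties=prop.parent_properties,
            )
        )
    for (a, b) in pre.subclass_closure:
        if a != b:
            flat.axioms.append(SubClassOf(Named(a), Named(b)))
    for prop, pairs in pre.property_closures.items():
        for (a, b) in pairs:
            flat.axioms.append(SubClassOf(Named(a), Existential(prop, Named(b))))
    flat.validate()
    return dumps_obo(flat)


def write_closure(pre: PreReasonedOntology, path: str | Path, format: str = "tsv") -> None:
    """Write a pre-reasoned ontology as sorted TSV or materialized OBO."""
    if format == "tsv":
        text = dumps_closure_tsv(pre)
    elif format == "obo":
        text = dumps_closure_obo(pre)
    else:
        raise ConfigurationError(f"unknown closure format {format!r}")
    Path(path).write_text(text, encoding="utf-8")
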