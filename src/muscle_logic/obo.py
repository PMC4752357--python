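"""Reading and writing the OBO-dialect exchange format.

The dialect is standard OBO flat-file syntax for ``[Term]`` and
``[Typedef]`` stanzas, with two documented extensions needed to carry the
full EL axiom set:

* a nonstandard ``[gci]`` stanza with ``sub:`` / ``sup:`` class-expression
  strings (general class inclusions are not expressible in Term stanzas);
* an ``equivalent_to: <expression>`` Term tag for equivalence definitions
  that do not fit ``intersection_of`` lines (e.g. a definition that is a
  bare conjunction of existentials with no named genus, like the muscle
  definitions built from attachments + innervation only).

Expression strings use the same grammar as DL queries (one parser owns the
grammar, so files and queries round-trip bit-exactly). Output is
deterministic: stanzas sorted by CURIE, tags in fixed order — re-reading
reproduces the input structurally.
"""

from __future__ import annotations

import re
from pathlib import Path

from .errors import OboParseError
from .expressions import parse_expression, render_expression
from .model import (
    Axiom,
    Conjunction,
    Curie,
    EquivalentTo,
    Existential,
    Named,
    ObjectProperty,
    Ontology,
    OntologyClass,
    SubClassOf,
)

__all__ = ["read_obo", "write_obo", "dumps_obo", "loads_obo"]

_HEADER = "format-version: 1.2"

_TERM_TAGS = {
    "id",
    "name",
    "def",
    "synonym",
    "xref",
    "is_a",
    "relationship",
    "intersection_of",
    "equivalent_to",
}
_TYPEDEF_TAGS = {"id", "name", "is_transitive", "is_a"}

_DEF_RE = re.compile(r'^"(?P<text>.*)"\s*(?:\[(?P<src>[^\]]*)\])?\s*$')
_SYN_RE = re.compile(r'^"(?P<text>.*)"')


def _strip_comment(value: str) -> str:
    return value.split(" ! ", 1)[0].rstrip("!").strip()


def _parse_curie(value: str, line: int) -> Curie:
    try:
        return Curie.parse(_strip_comment(value))
    except ValueError as exc:
        raise OboParseError(str(exc), line) from None


def loads_obo(text: str, source: str = "<string>") -> Ontology:
    """Parse OBO-dialect text into a validated :class:`Ontology`."""
    stanzas: list[tuple[str, int, list[tuple[str, str, int]]]] = []
    current: list[tuple[str, str, int]] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line.lstrip().startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            kind = line[1:-1]
            if kind not in ("Term", "Typedef", "gci"):
                raise OboParseError(f"unknown stanza type {kind!r}", lineno)
            current = []
            stanzas.append((kind, lineno, current))
            continue
        if ":" not in line:
            if current is None:
                raise OboParseError(f"malformed header line {line!r}", lineno)
            raise OboParseError(f"malformed tag line {line!r} (missing ':')", lineno)
        tag, value = line.split(":", 1)
        tag, value = tag.strip(), value.strip()
        if current is None:
            continue  # header tags (format-version, ontology, ...) are not modeled
        current.append((tag, value, lineno))

    ontology = Ontology()
    term_bodies: list[tuple[Curie, list[tuple[str, str, int]]]] = []
    gci_bodies: list[tuple[int, list[tuple[str, str, int]]]] = []

    # pass 1: declarations
    for kind, start, tags in stanzas:
        if kind == "gci":
            gci_bodies.append((start, tags))
            continue
        by_tag: dict[str, list[tuple[str, int]]] = {}
        for tag, value, lineno in tags:
            by_tag.setdefault(tag, []).append((value, lineno))
        if "id" not in by_tag:
            raise OboParseError(f"[{kind}] stanza without an id tag", start)
        ident = _parse_curie(by_tag["id"][0][0], by_tag["id"][0][1])
        if "name" not in by_tag:
            raise OboParseError(f"[{kind}] {ident} has no name tag", start)
        name = by_tag["name"][0][0]
        if kind == "Typedef":
            transitive = any(
                v.strip().lower() == "true" for v, _ in by_tag.get("is_transitive", [])
            )
            parents = tuple(
                _parse_curie(v, ln) for v, ln in by_tag.get("is_a", [])
            )
            ontology.add_property(
                ObjectProperty(ident, name, is_transitive=transitive, parent_properties=parents)
            )
            continue
        text_def = def_source = None
        if "def" in by_tag:
            value, ln = by_tag["def"][0]
            m = _DEF_RE.match(value)
            if not m:
                raise OboParseError(f"malformed def line {value!r}", ln)
            text_def = m.group("text")
            def_source = m.group("src") or None
        synonyms = []
        for value, ln in by_tag.get("synonym", []):
            m = _SYN_RE.match(value)
            if not m:
                raise OboParseError(f"malformed synonym line {value!r}", ln)
            synonyms.append(m.group("text"))
        xrefs = tuple(_parse_curie(v, ln) for v, ln in by_tag.get("xref", []))
        annotations = tuple(
            (tag, value)
            for tag, value, _ in tags
            if tag not in _TERM_TAGS
        )
        ontology.add_class(
            OntologyClass(
                id=ident,
                label=name,
                synonyms=tuple(synonyms),
                xrefs=xrefs,
                text_def=text_def,
                def_source=def_source,
                annotations=annotations,
            )
        )
        term_bodies.append((ident, tags))

    # pass 2: axioms (labels in expression strings need the full vocabulary)
    for ident, tags in term_bodies:
        intersection: list = []
        for tag, value, lineno in tags:
            if tag == "is_a":
                ontology.axioms.append(
                    SubClassOf(Named(ident), Named(_parse_curie(value, lineno)))
                )
            elif tag == "relationship":
                parts = _strip_comment(value).split()
                if len(parts) != 2:
                    raise OboParseError(
                        f"malformed relationship line {value!r}", lineno
                    )
                prop = _parse_curie(parts[0], lineno)
                target = _parse_curie(parts[1], lineno)
                ontology.axioms.append(
                    SubClassOf(Named(ident), Existential(prop, Named(target)))
                )
            elif tag == "intersection_of":
                parts = _strip_comment(value).split()
                if len(parts) == 1:
                    intersection.append(Named(_parse_curie(parts[0], lineno)))
                elif len(parts) == 2:
                    prop = _parse_curie(parts[0], lineno)
                    filler = _parse_curie(parts[1], lineno)
                    intersection.append(Existential(prop, Named(filler)))
                else:
                    raise OboParseError(
                        f"malformed intersection_of line {value!r}", lineno
                    )
            elif tag == "equivalent_to":
                expr = parse_expression(value, ontology)
                ontology.axioms.append(EquivalentTo(ident, expr))
        if intersection:
            if len(intersection) < 2:
                raise OboParseError(
                    f"term {ident} has a single intersection_of line", tags[0][2]
                )
            from .model import conjunction_of

            ontology.axioms.append(EquivalentTo(ident, conjunction_of(intersection)))

    for start, tags in gci_bodies:
        by_tag = {tag: (value, ln) for tag, value, ln in tags}
        if "sub" not in by_tag or "sup" not in by_tag:
            raise OboParseError("[gci] stanza needs both sub: and sup:", start)
        sub = parse_expression(by_tag["sub"][0], ontology)
        sup = parse_expression(by_tag["sup"][0], ontology)
        ontology.axioms.append(SubClassOf(sub, sup))

    ontology.validate()
    return ontology


def read_obo(path: str | Path) -> Ontology:
    """Read an OBO-dialect file (UTF-8) into a validated :class:`Ontology`."""
    path = Path(path)
    return loads_obo(path.read_text(encoding="utf-8"), source=str(path))


# --------------------------------------------------------------------------
# Writing


def _is_simple_existential(expr) -> bool:
    return isinstance(expr, Existential) and isinstance(expr.filler, Named)


def _intersection_compatible(expr) -> bool:
    return isinstance(expr, Conjunction) and all(
        isinstance(c, Named) or _is_simple_existential(c) for c in expr.conjuncts
    )


def dumps_obo(ontology: Ontology) -> str:
    """Serialize deterministically: stanzas sorted by CURIE, fixed tag order."""
    is_a: dict[Curie, list[Curie]] = {}
    relationships: dict[Curie, list[tuple[Curie, Curie]]] = {}
    equivalences: dict[Curie, list] = {}
    gcis: list[SubClassOf] = []
    for axiom in ontology.axioms:
        if isinstance(axiom, EquivalentTo):
            equivalences.setdefault(axiom.cls, []).append(axiom.definition)
        elif isinstance(axiom.sub, Named) and isinstance(axiom.sup, Named):
            is_a.setdefault(axiom.sub.cls, []).append(axiom.sup.cls)
        elif isinstance(axiom.sub, Named) and _is_simple_existential(axiom.sup):
            relationships.setdefault(axiom.sub.cls, []).append(
                (axiom.sup.prop, axiom.sup.filler.cls)
            )
        else:
            gcis.append(axiom)

    lines: list[str] = [_HEADER]

    for cid in sorted(ontology.classes, key=str):
        cls = ontology.classes[cid]
        lines.append("")
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        lines.append(f"name: {cls.label}")
        if cls.text_def is not None:
            src = cls.def_source or ""
            lines.append(f'def: "{cls.text_def}" [{src}]')
        for syn in sorted(cls.synonyms):
            lines.append(f'synonym: "{syn}" EXACT []')
        for xref in sorted(cls.xrefs, key=str):
            lines.append(f"xref: {xref}")
        for parent in sorted(is_a.get(cid, []), key=str):
            lines.append(f"is_a: {parent} ! {ontology.label_of(parent)}")
        defs = equivalences.get(cid, [])
        if len(defs) == 1 and _intersection_compatible(defs[0]):
            for conjunct in defs[0].conjuncts:
                if isinstance(conjunct, Named):
                    lines.append(
                        f"intersection_of: {conjunct.cls}"
                        f" ! {ontology.label_of(conjunct.cls)}"
                    )
                else:
                    lines.append(
                        f"intersection_of: {conjunct.prop} {conjunct.filler.cls}"
                        f" ! {ontology.label_of(conjunct.filler.cls)}"
                    )
        else:
            for definition in sorted(
                (render_expression(d, ontology) for d in defs)
            ):
                lines.append(f"equivalent_to: {definition}")
        for prop, target in sorted(
            relationships.get(cid, []), key=lambda pt: (str(pt[0]), str(pt[1]))
        ):
            lines.append(
                f"relationship: {prop} {target} ! {ontology.label_of(target)}"
            )
        for tag, value in sorted(cls.annotations):
            lines.append(f"{tag}: {value}")

    for pid in sorted(ontology.properties, key=str):
        prop = ontology.properties[pid]
        lines.append("")
        lines.append("[Typedef]")
        lines.append(f"id: {pid}")
        lines.append(f"name: {prop.label}")
        if prop.is_transitive:
            lines.append("is_transitive: true")
        for parent in sorted(prop.parent_properties, key=str):
            lines.append(f"is_a: {parent}")

    rendered_gcis = sorted(
        (
            render_expression(g.sub, ontology),
            render_expression(g.sup, ontology),
        )
        for g in gcis
    )
    for sub, sup in rendered_gcis:
        lines.append("")
        lines.append("[gci]")
        lines.append(f"sub: {sub}")
        lines.append(f"sup: {sup}")

    return "\n".join(lines) + "\n"


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Write an ontology to ``path``; ``read_obo`` reproduces it structurally."""
    Path(path).write_text(dumps_obo(ontology), encoding="utf-8")
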