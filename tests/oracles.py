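"""Independent oracles: a naive all-pairs fixpoint reasoner, a derivation
replay checker, and a networkx transitive-closure routine.

These deliberately share no code or strategy with the package reasoner:
the naive oracle rescans every rule over every class until nothing
changes, with no normalization sharing (it re-normalizes through the
package's normal forms but applies the semantics by brute force).
"""

from __future__ import annotations

import networkx as nx

from muscle_logic.model import Curie, Ontology
from muscle_logic.reasoner import (
    NF1,
    NF2,
    NF3,
    NF4,
    TOP,
    DerivationTrace,
    NormalAxiom,
    normalize,
)


def naive_saturate(ontology: Ontology) -> dict[Curie, frozenset[Curie]]:
    """Brute-force least fixpoint of the EL completion rules.

    Returns the subsumer sets restricted to the ontology's named classes
    (fresh normalization names and the implicit top are stripped).
    """
    axioms = normalize(ontology)
    universe: set[Curie] = set(ontology.classes)
    for ax in axioms:
        if isinstance(ax, NF1):
            universe |= {ax.sub, ax.sup}
        elif isinstance(ax, NF2):
            universe |= {ax.a1, ax.a2, ax.sup}
        elif isinstance(ax, NF3):
            universe |= {ax.sub, ax.filler}
        else:
            universe |= {ax.filler, ax.sup}

    S = {c: {c, TOP} for c in universe}
    R: dict[Curie, set[tuple[Curie, Curie]]] = {}

    ancestors: dict[Curie, set[Curie]] = {}
    for pid in ontology.properties:
        seen: set[Curie] = set()
        stack = list(ontology.properties[pid].parent_properties)
        while stack:
            parent = stack.pop()
            if parent not in seen:
                seen.add(parent)
                stack.extend(ontology.properties[parent].parent_properties)
        ancestors[pid] = seen

    changed = True
    while changed:
        changed = False
        for ax in axioms:
            if isinstance(ax, NF1):
                for a in universe:
                    if ax.sub in S[a] and ax.sup not in S[a]:
                        S[a].add(ax.sup)
                        changed = True
            elif isinstance(ax, NF2):
                for a in universe:
                    if ax.a1 in S[a] and ax.a2 in S[a] and ax.sup not in S[a]:
                        S[a].add(ax.sup)
                        changed = True
            elif isinstance(ax, NF3):
                bucket = R.setdefault(ax.prop, set())
                for a in universe:
                    if ax.sub in S[a] and (a, ax.filler) not in bucket:
                        bucket.add((a, ax.filler))
                        changed = True
            else:  # NF4
                for (a, b) in list(R.get(ax.prop, ())):
                    if ax.filler in S[b] and ax.sup not in S[a]:
                        S[a].add(ax.sup)
                        changed = True
        for prop, pairs in list(R.items()):
            if prop in ontology.properties and ontology.properties[prop].is_transitive:
                for (a, b) in list(pairs):
                    for (b2, c) in list(pairs):
                        if b2 == b and (a, c) not in pairs:
                            pairs.add((a, c))
                            changed = True
            for parent in ancestors.get(prop, ()):
                bucket = R.setdefault(parent, set())
                for pair in pairs:
                    if pair not in bucket:
                        bucket.add(pair)
                        changed = True

    named = set(ontology.classes)
    return {c: frozenset(S[c] & named) for c in named}


def package_subsumers(ontology: Ontology) -> dict[Curie, frozenset[Curie]]:
    """The package reasoner's subsumer sets in the oracle's shape."""
    from muscle_logic.reasoner import classify

    sat = classify(ontology)
    return {c: sat.subsumers_of(c) for c in ontology.classes}


# --------------------------------------------------------------------------
# Trace replay


def replay_trace(trace: DerivationTrace, axioms: set[NormalAxiom], properties) -> bool:
    """Verify a derivation bottom-up: every axiom premise must be asserted
    and every step must be a correct instance of its rule."""
    for p in trace.premises:
        if isinstance(p, DerivationTrace):
            if not replay_trace(p, axioms, properties):
                return False
        elif p not in axioms:
            return False

    concl = trace.conclusion
    prem = [
        p.conclusion if isinstance(p, DerivationTrace) else p for p in trace.premises
    ]
    rule = trace.rule
    if rule == "init":
        return concl[0] == "S" and concl[1] == concl[2]
    if rule == "top":
        return concl[0] == "S" and concl[2] == TOP
    if rule == "R1":
        (fact, ax) = prem
        return (
            isinstance(ax, NF1)
            and fact == ("S", concl[1], ax.sub)
            and concl == ("S", concl[1], ax.sup)
        )
    if rule == "R2":
        (f1, f2, ax) = prem
        return (
            isinstance(ax, NF2)
            and f1 == ("S", concl[1], ax.a1)
            and f2 == ("S", concl[1], ax.a2)
            and concl == ("S", concl[1], ax.sup)
        )
    if rule == "R3":
        (fact, ax) = prem
        return (
            isinstance(ax, NF3)
            and concl[0] == "R"
            and fact == ("S", concl[2], ax.sub)
            and concl == ("R", ax.prop, concl[2], ax.filler)
        )
    if rule == "R4":
        (rf, sf, ax) = prem
        return (
            isinstance(ax, NF4)
            and rf[0] == "R"
            and sf[0] == "S"
            and rf[1] == ax.prop
            and rf[2] == concl[1]
            and sf[1] == rf[3]
            and sf[2] == ax.filler
            and concl == ("S", concl[1], ax.sup)
        )
    if rule == "R5":
        (f1, f2) = prem
        r = concl[1]
        prop = properties.get(r)
        return (
            prop is not None
            and prop.is_transitive
            and f1 == ("R", r, concl[2], f1[3])
            and f2 == ("R", r, f1[3], concl[3])
        )
    if rule == "R6":
        (fact,) = prem
        r = fact[1]
        s = concl[1]
        ancestors = set()
        stack = list(properties[r].parent_properties)
        while stack:
            parent = stack.pop()
            if parent not in ancestors:
                ancestors.add(parent)
                stack.extend(properties[parent].parent_properties)
        return s in ancestors and concl == ("R", s, fact[2], fact[3])
    return False


# --------------------------------------------------------------------------
# Graph closure


def graph_transitive_closure(pairs) -> frozenset:
    """Reflexive-free transitive closure of a pair set via networkx."""
    g = nx.DiGraph()
    g.add_edges_from(pairs)
    closure = nx.transitive_closure(g, reflexive=False)
    return frozenset(closure.edges())
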