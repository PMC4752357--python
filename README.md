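# muscle-logic

Computable comparative anatomy for the feeding muscles of mammals: an
anatomy-ontology toolkit in which each muscle carries a
necessary-and-sufficient logical definition built from its attachments and
innervation, a polynomial-time EL reasoner classifies the hierarchy, and the
resulting knowledge powers both DL queries and ontology-expanded literature
search.

## Who this is for

Comparative anatomists and ontology engineers who want questions phrased in
the language of the field — *which muscles attach to the mandible?*, *which
muscles develop from the first branchial arch?* — answered by machine
reasoning rather than by hand-curated lists, and who want literature search
that knows the temporalis is a trigeminal muscle and that the external
pterygoid *is* the lateral pterygoid. Keyword engines can do neither.

## The model

Muscle classes are defined in the EL fragment of OWL. A definition has the
template

```
M ≡ (innervated_by some Nerve) ⊓ (attached_to some BoneA) ⊓ (attached_to some BoneB)
```

e.g. the styloglossus ≡ ∃innervated_by.'hypoglossal nerve' ⊓
∃attached_to.'stylohyal bone' ⊓ ∃attached_to.tongue. Because the conditions
are necessary *and* sufficient, the reasoner can both check and discover
membership. Developmental origin is not asserted per muscle; it follows from
a general class inclusion (GCI):

```
∃innervated_by.'trigeminal nerve' ⊑ ∃develops_from.'branchial arch 1'
∃innervated_by.'facial nerve'     ⊑ ∃develops_from.'branchial arch 2'
```

Classification works by rewriting all axioms into the four EL normal forms
(A ⊑ B, A₁ ⊓ A₂ ⊑ B, A ⊑ ∃r.B, ∃r.A ⊑ B) and saturating subsumer sets S(·)
and role-pair sets R(·) under the standard completion rules, including role
transitivity (`part_of`) and the property hierarchy. Every inference carries
a replayable derivation trace.

The package ships a fixture ontology containing the documented subset of the
Mammalian Feeding Muscle Ontology (MFMO), built programmatically with a
per-axiom citation manifest (`muscle_logic.fixture`).

## Worked example

```python
from muscle_logic import build_fixture, classify, answer_text

onto = build_fixture()
sat = classify(onto)
res = answer_text("'muscle organ' and ('develops from' some 'branchial arch 1')",
                  onto, sat)
print(len(res.all_answers))        # 20
print(sorted(res.labels(onto))[:3])
# ['anterior digastric muscle', 'anterior masseter muscle', 'deep masseter muscle']
```

The 20 answers are the trigeminal muscles — including the grouping class
`trigeminal muscle` itself — and **every one is inferred**: no muscle in the
ontology has a direct `develops_from` axiom, so the answers exist only
because each muscle's trigeminal innervation feeds the arch-origin GCI.

Running `python examples/competency_queries.py` prints all three competency
answer sets (26, 20 and 17 classes); `examples/explain_inferences.py` prints
the rule-by-rule derivations (the epiphysis-of-digit ⊑ epiphysis-of-hand
proof uses the `part_of` transitivity rule); and
`examples/semantic_vs_keyword_search.py` prints, on a generated corpus where
half the relevant abstracts use the synonym 'external pterygoid muscle':

```
semantic search: recall=1.00 precision=1.00
keyword search:  recall=0.60 precision=1.00
```

The two single-feature mandible/arch-1 answer sets differ from the
corresponding published tables by exactly one class each (the transversus
mandibulae and the mylohyoid) because the published tables are mutually
inconsistent about those two muscles; the package returns the logically
consistent sets and the tests pin the deltas. See `docs/methods.md`.

A thin CLI mirrors the library: `muscle-logic validate|labels|classify|
query|closure|fixture|gen-corpus|search` (see `muscle-logic --help`).

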