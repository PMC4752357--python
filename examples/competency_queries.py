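"""Answer the three competency DL queries against the bundled ontology.

Builds the feeding-muscle fixture, classifies it with the EL reasoner,
and runs the three anatomist-style questions: which muscles attach to the
mandible, which develop from the first branchial arch, and the
conjunction of the two. The printed counts are the sizes of the entailed
answer sets; no muscle carries a direct developmental-origin axiom, so
every arch-1 answer is inferred through the innervation rule.
"""

from muscle_logic import answer_text, build_fixture, classify

onto = build_fixture()
sat = classify(onto)

queries = {
    "attached to the mandible": "'muscle organ' and ('attached to' some 'mandible')",
    "develop from branchial arch 1": "'muscle organ' and ('develops from' some 'branchial arch 1')",
    "trigeminal muscles attached to the mandible": (
        "'muscle organ' and ('innervated by' some 'trigeminal nerve') "
        "and ('attached_to' some 'mandible bone')"
    ),
}

for name, text in queries.items():
    result = answer_text(text, onto, sat)
    print(f"Muscles that {name}: {len(result.all_answers)}")
    for label in result.labels(onto):
        print(f"  - {label}")
    print()
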