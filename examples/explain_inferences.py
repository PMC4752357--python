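"""Show two automatic classifications with their derivations.

First, the classic part_of example: the epiphysis of a digit is
classified under the epiphysis of the hand because a digit is part of
the hand and part_of chains compose. Second, the developmental-origin
inference: the posterior digastric muscle is derived from the second
branchial arch solely because it is innervated by the facial nerve.
The printed trace lists each completion-rule application bottom-up.
"""

from muscle_logic import Existential, Named, build_fixture, classify, entails, explain
from muscle_logic.fixture import ARCH2, DEVELOPS_FROM
from muscle_logic.reasoner import DerivationTrace, explain_role

onto = build_fixture()
sat = classify(onto)


def show(trace: DerivationTrace, depth: int = 0) -> None:
    kind = trace.conclusion[0]
    if kind == "S":
        _, a, b = trace.conclusion
        concl = f"{onto.label_of(a)} ⊑ {onto.label_of(b)}"
    else:
        _, r, a, b = trace.conclusion
        concl = f"{onto.label_of(a)} ⊑ ∃{onto.label_of(r)}.{onto.label_of(b)}"
    print("  " * depth + f"[{trace.rule}] {concl}")
    for premise in trace.premises:
        if isinstance(premise, DerivationTrace):
            show(premise, depth + 1)


eod = onto.resolve_label("epiphysis of digit")
eoh = onto.resolve_label("epiphysis of hand")
print(f"entailed: epiphysis of digit ⊑ epiphysis of hand -> {sat.is_entailed(eod, eoh)}")
show(explain(sat, eod, eoh))
print()

pd = onto.resolve_label("posterior digastric muscle")
ok = entails(onto, Named(pd), Existential(DEVELOPS_FROM, Named(ARCH2)))
print(f"entailed: posterior digastric ⊑ ∃develops_from.'branchial arch 2' -> {ok}")
show(explain_role(sat, DEVELOPS_FROM, pd, ARCH2))
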